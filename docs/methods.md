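# Methods

## The measurement model

All analyses assume a crossed two-way random-effects model for a
shear-modulus reading on subject *i* (i = 1..n) by operator *j*
(j = 1, 2), replicate *r* (r = 1..3):

    y_ijr = μ + s_i + o_j + so_ij + e_ijr

with independent zero-mean Gaussian effects of variances σ²_s
(subject), σ²_o (operator), σ²_so (interaction) and σ²_e (replicate
noise), all in kPa². The synthetic cohort generator draws from exactly
this model, so every estimator in the package has a known target:

- inter-operator absolute-agreement ICC of a single measurement:
  ρ_A = σ²_s / (σ²_s + σ²_o + σ²_so + σ²_e);
- intra-operator (test-retest) ICC: 1 − σ²_e / total, treating the
  subject-by-operator level as the stable quantity.

Gaussian effects were chosen for tractable moments; published
reliability tables in this field report only per-muscle means and SDs,
which constrain μ and the total variance but not the distribution
shape. Generated values are floored at 0.1 kPa — a physical
plausibility floor far below relaxed-muscle stiffness (≥ ~11 kPa) — so
the floor is effectively never active at realistic settings.

## Default study conditions

The default synthetic study mirrors a three-cohort two-operator
design: a training set of 16 healthy subjects (3 muscles × 2 views,
triplicates, no missingness), a validation set of 15 healthy subjects
and an ICU set of 12 patients. The ICU defaults use grand means
13.7 / 17.8 / 16.6 kPa (diaphragm, biceps brachii, rectus femoris) with
variance splits (σ²_s, σ²_o, σ²_so, σ²_e) of (11.5, 0.2, 0.3, 0.5),
(9.6, 0.1, 0.1, 0.2) and (9.1, 0.3, 0.2, 0.4) kPa² — true agreement
ICCs of 0.92, 0.96 and 0.91. Training components are calibrated so one
view per muscle is clearly more reliable (e.g. diaphragm longitudinal
ρ_A = 0.83 vs transverse 0.30), which exercises the view-selection
stage. Validation and ICU cohorts use a 3% completely-at-random
missing rate, emulating occasionally uninterpretable acquisitions;
real dropout is unlikely to be fully random (it plausibly correlates
with oedema or agitation), a mechanism the generator does not model.
Consequently, passing tests demonstrate correct estimation under the
assumed variance structure, not robustness to informative missingness,
non-Gaussian stiffness distributions or anisotropy effects.

## ICC estimation

**Intra-operator** reliability uses the one-way random-effects
single-measure ICC(1) across the three replicates, because replicates
of one operator are exchangeable — there is no replicate "rater"
effect to model. Estimate (MSB − MSW)/(MSB + (k−1)MSW); the CI inverts
F = MSB/MSW against F(n−1, N−n) quantiles at α/2 per tail. Unbalanced
replicate counts use cell-available data with the effective-k
correction k₀ = (N − Σn_i²/N)/(n−1).

**Inter-operator** reproducibility uses the two-way random-effects,
absolute-agreement, single-measure ICC(A,1): operators are a random
sample of possible raters, and comparing absolute stiffness values
between operators means systematic offsets must count against
reliability (the consistency form ICC(C,1), which forgives offsets, is
provided for comparison and is always ≥ the agreement form under an
offset). By default ICC(A,1) is computed on per-operator triplicate
means, matching how such studies summarise each operator's assessment;
a replicate-level mode estimates single-measurement reliability from
the full crossed ANOVA with replication (unbiased method-of-moments
variance components from MS_S, MS_O, MS_SO, MS_E). Note the two modes
estimate different population quantities: means-mode reliability
replaces σ²_e by σ²_e/3 in the denominator. Both are useful; the
means-mode is the pipeline default.

The agreement CI generalises the Satterthwaite construction: the
subjects mean square is compared against the linear combination of the
remaining mean squares whose expectation matches it under the
hypothesised ρ (MS\* = MS_SO + τ·R with τ = k·m·ρ/(1−ρ)); bounds solve
MS_S = F·MS\* in closed form, with Satterthwaite degrees of freedom
evaluated at the plug-in estimate. With m = 1 this reduces exactly to
the classical single-measure absolute-agreement interval (verified
against pingouin in the test suite).

Numerical edge cases: a constant matrix raises `IccUndefinedError`
(all variance gone, the coefficient is undefined); zero error variance
returns a degenerate estimate and CI of 1; negative estimates are
reported as computed — not truncated at zero — and classified "poor".
Degeneracy is detected at relative tolerance 1e-12 of the data scale.

## Agreement and comparisons

Bland-Altman uses the mean paired difference, the n−1 SD of
differences and limits of agreement at ±1.96 SD (the conventional
large-sample multiplier; no small-sample t correction). Operator
comparisons are gated on a normality check of the paired differences:
Kolmogorov-Smirnov against a normal with the sample mean/SD by default
— the convention in clinical reports, though anti-conservative because
the parameters are estimated; the Lilliefors-corrected variant is
available and is the statistically proper choice. Differences passing
the gate go to a paired t test, otherwise to the Wilcoxon
matched-pairs signed-rank test. Unpaired variants (Student's t /
Mann-Whitney) are retained for cross-cohort contrasts only. Every gate
decision is logged by the pipeline.

## Bootstrap consistency

The bootstrap resamples *subjects* (matrix rows) with replacement,
keeping each subject's operator pairing intact — resampling individual
measurements would destroy the paired structure the ICC describes.
Per resample the agreement ICC is recomputed (vectorised over all
resamples); the summary is the fraction reaching the threshold
(default 0.8). Resamples with a constant matrix (e.g. one distinct
subject drawn n times under perfect agreement) leave the ICC
undefined; they are counted and treated as below threshold, keeping
the probability conservative rather than silently discarding them.
Deterministic given (data, seed, n_boot); at 10,000 resamples the
Monte-Carlo SE of the probability is ≤ 0.005.

## Sample-size planning

The Walter-Eliasziw-Donner approximation powers a one- or two-sided
test of ρ ≥ ρ₀ against ρ₁: with θ = ρ/(1−ρ) and
C₀ = (1 + kθ₀)/(1 + kθ₁), n = 1 + 2(z_α + z_β)²k/((ln C₀)²(k−1)),
rounded up. ρ₀ is a required input: a reliability target alone does
not determine a sample size, and published studies often omit the null
value they used. An inflation fraction (e.g. 25% for anticipated
uninterpretable images) scales the requirement with ceiling rounding.

## View selection

Per muscle, the view with the higher training-set inter-operator ICC
is selected. Exact ties — or overlapping 95% CIs under the
`ci_overlap` policy — resolve toward the longitudinal view, the
conventional imaging plane for these muscles. The margin and decision
are logged; an override lets users force a view (relevant when the two
views are statistically indistinguishable, as happens for the rectus
femoris at training-set sizes).

## Seeds and reproducibility

One global seed drives everything: `numpy.random.SeedSequence.spawn`
derives independent substreams per cohort and for the bootstrap, so
each cohort is independently reproducible and a full synthetic run is
bit-identical across repeats (the report timestamp is the only
changing field).

## Problem sizes

Stochastic guarantees in the test suite use sizes chosen to make
Monte-Carlo error small relative to the asserted tolerance: parameter
recovery averages 500 simulated 12-subject cohorts per variance
setting (SE of the mean ≈ 0.002, tolerance ±0.02); the type-I
calibration of the gated comparison uses 2,000 paired null replicates
at n = 16 (binomial SE ≈ 0.005, tolerance ±0.02); bootstrap exactness
is checked at the full 10,000 resamples.

## Known limitations

- The generator does not model muscle anisotropy, probe-pressure
  artefacts, depth-dependent speckle or informative missingness.
- The replicate-level agreement CI is an approximation (Satterthwaite
  across three error strata); coverage is exact only in the m = 1
  reduction.
- The Kolmogorov-Smirnov default for normality is anti-conservative
  with estimated parameters; use `normality_method="lilliefors"` when
  the gate matters.
- Elastogram synthesis is a band-layout speckle model for testing ROI
  quantification, not a wave-propagation simulation.
- No REML/Bayesian variance-component estimation; unbalanced two-way
  designs are handled by cell means, not full unbalanced ANOVA.
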