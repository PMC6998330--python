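"""Intraclass correlation coefficients from ANOVA mean squares.

Two estimators cover the study design:

* ``icc_oneway`` — one-way random-effects, single-measure ICC(1) for
  intra-operator repeatability across exchangeable replicates:
  (MSB - MSW) / (MSB + (k-1) MSW), with an exact F-based confidence
  interval on (n-1, N-n) degrees of freedom.  Unbalanced replicate
  counts are handled with the standard effective-k correction
  k0 = (N - sum(n_i^2)/N) / (n-1).

* ``icc_twoway_agreement`` — two-way random-effects, absolute-agreement,
  single-measure ICC(A,1) for inter-operator reproducibility.  Given an
  n x k matrix of per-operator values the point estimate is
  (MS_S - MS_E) / (MS_S + (k-1) MS_E + (k/n)(MS_O - MS_E)) and the CI
  uses the Satterthwaite-approximated denominator degrees of freedom.
  Given an n x k x m array of raw replicates, the same coefficient is
  estimated from the full crossed ANOVA with replication (subject,
  operator, interaction and residual mean squares), targeting the
  reliability of a *single* measurement rather than of a replicate
  mean; the CI generalises the Satterthwaite construction to the extra
  stratum and reduces exactly to the classical formula when m = 1.

* ``icc_twoway_consistency`` — ICC(C,1), which ignores systematic
  operator offsets; provided for comparison (agreement <= consistency
  whenever a rater offset exists).

Negative estimates are reported as computed (not truncated at zero) and
fall in the 'poor' agreement band.  Estimates are classified on the
conventional reliability scale: below 0.50 poor, 0.50-0.74 moderate,
0.75-0.89 good, 0.90 and above excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

_BANDS = (
    (0.50, "poor"),
    (0.75, "moderate"),
    (0.90, "good"),
    (np.inf, "excellent"),
)

#: Relative tolerance under which a matrix counts as constant (ICC undefined).
_DEGENERATE_RTOL = 1e-12


class IccUndefinedError(ValueError):
    """All variance vanished: the ICC is not defined."""


def classify_icc(estimate: float) -> str:
    """Reliability band of an ICC estimate.

    Half-open bands: (-inf, 0.50) poor, [0.50, 0.75) moderate,
    [0.75, 0.90) good, [0.90, inf) excellent.  Negative estimates are
    'poor'.
    """
    for upper, band in _BANDS:
        if estimate < upper:
            return band
    return "excellent"  # pragma: no cover


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares and degrees of freedom of the reliability ANOVA.

    For the one-way model only ``ms_subjects``/``ms_within`` are set;
    for the two-way model ``ms_error`` is the interaction-plus-residual
    term (cell-means input) or the pure residual (replicated input, in
    which case ``ms_interaction`` is also populated).
    """

    n_subjects: int
    k_raters: int
    ms_subjects: float
    df_subjects: float
    ms_within: Optional[float] = None
    df_within: Optional[float] = None
    ms_raters: Optional[float] = None
    df_raters: Optional[float] = None
    ms_error: Optional[float] = None
    df_error: Optional[float] = None
    ms_interaction: Optional[float] = None
    df_interaction: Optional[float] = None
    m_replicates: int = 1


@dataclass(frozen=True)
class IccResult:
    """An ICC point estimate with its confidence interval and band."""

    estimate: float
    ci_low: float
    ci_high: float
    model: str
    alpha: float
    band: str
    anova: AnovaDecomposition

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")


def _as_matrix(matrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("matrix contains NaN; aggregate or drop incomplete cells first")
    return arr


def icc_oneway(matrix, alpha: float = 0.05) -> IccResult:
    """One-way random-effects single-measure ICC(1) with exact F CI.

    ``matrix`` is n subjects x k replicates; NaN marks a missing
    replicate (rows need at least one value, and at least one row needs
    two).  The CI inverts F = MSB/MSW against F(n-1, N-n) quantiles at
    alpha/2 per tail.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an n x k matrix")
    counts = np.sum(~np.isnan(arr), axis=1)
    arr = arr[counts > 0]
    counts = counts[counts > 0]
    n = arr.shape[0]
    N = int(counts.sum())
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if N - n < 1:
        raise ValueError("need at least 2 replicates for at least one subject")
    grand = np.nansum(arr) / N
    means = np.nanmean(arr, axis=1)
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.nansum((arr - means[:, None]) ** 2))
    df_b, df_w = n - 1, N - n
    msb, msw = ssb / df_b, ssw / df_w
    scale = max(abs(grand), 1.0)
    if ssb + ssw <= _DEGENERATE_RTOL * scale**2:
        raise IccUndefinedError("constant matrix: one-way ICC undefined")
    k0 = (N - float(np.sum(counts**2)) / N) / df_b
    if msw == 0.0:
        est, lo, hi = 1.0, 1.0, 1.0
    else:
        est = (msb - msw) / (msb + (k0 - 1.0) * msw)
        f_obs = msb / msw
        f_low = f_obs / stats.f.ppf(1 - alpha / 2, df_b, df_w)
        f_high = f_obs * stats.f.ppf(1 - alpha / 2, df_w, df_b)
        lo = (f_low - 1.0) / (f_low + k0 - 1.0)
        hi = (f_high - 1.0) / (f_high + k0 - 1.0)
    anova = AnovaDecomposition(
        n_subjects=n,
        k_raters=arr.shape[1],
        ms_subjects=msb,
        df_subjects=df_b,
        ms_within=msw,
        df_within=df_w,
    )
    return IccResult(
        estimate=float(est),
        ci_low=float(min(lo, est)),
        ci_high=float(max(hi, est)),
        model="oneway_single",
        alpha=alpha,
        band=classify_icc(float(est)),
        anova=anova,
    )


def _crossed_anova(data: np.ndarray):
    """Mean squares of the crossed subject x rater ANOVA.

    ``data`` is n x k (cell means; the interaction absorbs the residual)
    or n x k x m (balanced replicates; four strata).  Returns
    (AnovaDecomposition, m).
    """
    if data.ndim == 2:
        data = data[:, :, None]
    n, k, m = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    grand = data.mean()
    mi = data.mean(axis=(1, 2))
    mj = data.mean(axis=(0, 2))
    mij = data.mean(axis=2)
    ss_s = k * m * float(np.sum((mi - grand) ** 2))
    ss_o = n * m * float(np.sum((mj - grand) ** 2))
    ss_so = m * float(np.sum((mij - mi[:, None] - mj[None, :] + grand) ** 2))
    ss_e = float(np.sum((data - mij[:, :, None]) ** 2))
    df_s, df_o, df_so = n - 1, k - 1, (n - 1) * (k - 1)
    df_e = n * k * (m - 1)
    scale = max(abs(grand), 1.0)
    if ss_s + ss_o + ss_so + ss_e <= _DEGENERATE_RTOL * scale**2:
        raise IccUndefinedError("constant matrix: two-way ICC undefined")
    dec = AnovaDecomposition(
        n_subjects=n,
        k_raters=k,
        ms_subjects=ss_s / df_s,
        df_subjects=df_s,
        ms_raters=ss_o / df_o,
        df_raters=df_o,
        ms_error=(ss_so / df_so) if m == 1 else (ss_e / df_e),
        df_error=df_so if m == 1 else df_e,
        ms_interaction=None if m == 1 else ss_so / df_so,
        df_interaction=None if m == 1 else df_so,
        m_replicates=m,
    )
    return dec, m


def _agreement_components(dec: AnovaDecomposition):
    """Unbiased variance-component estimates from the crossed ANOVA."""
    n, k, m = dec.n_subjects, dec.k_raters, dec.m_replicates
    if m == 1:
        ms_so, ms_e = dec.ms_error, None
        var_e = ms_so  # interaction + residual, inseparable
        var_so = 0.0
    else:
        ms_so, ms_e = dec.ms_interaction, dec.ms_error
        var_e = ms_e
        var_so = (ms_so - ms_e) / m
    var_s = (dec.ms_subjects - ms_so) / (k * m)
    var_o = (dec.ms_raters - ms_so) / (n * m)
    return var_s, var_o, var_so, var_e


def _agreement_ci(dec: AnovaDecomposition, est: float, alpha: float):
    """Satterthwaite F interval for the absolute-agreement ICC.

    Under the hypothesised coefficient rho the subjects mean square is
    compared with the matching linear combination of the rater,
    interaction and residual mean squares, MS* = MS_SO + tau * R with
    tau = k m rho / (1 - rho); the bounds solve MS_S = F * MS* in closed
    form.  With m = 1 this is exactly the classical single-measure
    absolute-agreement interval.
    """
    n, k, m = dec.n_subjects, dec.k_raters, dec.m_replicates
    ms_s, ms_o = dec.ms_subjects, dec.ms_raters
    if m == 1:
        ms_so, ms_e, df_so, df_e = dec.ms_error, 0.0, dec.df_error, 1.0
    else:
        ms_so, ms_e = dec.ms_interaction, dec.ms_error
        df_so, df_e = dec.df_interaction, dec.df_error
    # Linear-in-tau error combination: MS*(rho) = ms_so + tau * R
    R = ms_o / (n * m) + ms_so * (n - 1) / (n * m) + ms_e * (m - 1) / m
    if R <= 0:
        return est, est
    # Satterthwaite df of MS* at the plug-in estimate (clamped to [0, 1)).
    rho = min(max(est, 0.0), 1.0 - 1e-12)
    tau = k * m * rho / (1.0 - rho)
    a = tau / (n * m)
    b = 1.0 + tau / m - a
    c = tau * (1.0 - 1.0 / m)
    num = (a * ms_o + b * ms_so + c * ms_e) ** 2
    den = (a * ms_o) ** 2 / dec.df_raters + (b * ms_so) ** 2 / df_so
    if m > 1 and c > 0:
        den += (c * ms_e) ** 2 / df_e
    if den <= 0:
        return est, est
    v = num / den

    def _rho_at(ms_star_target: float) -> float:
        tau_b = (ms_star_target - ms_so) / R
        if not np.isfinite(tau_b) or tau_b <= -k * m:
            return -1.0
        r = tau_b / (tau_b + k * m)
        return float(np.clip(r, -1.0, 1.0))

    f_low = stats.f.ppf(1 - alpha / 2, dec.df_subjects, v)
    f_high = stats.f.ppf(1 - alpha / 2, v, dec.df_subjects)
    lo = _rho_at(ms_s / f_low)
    hi = _rho_at(ms_s * f_high)
    return lo, hi


def icc_twoway_agreement(data, alpha: float = 0.05) -> IccResult:
    """Two-way random-effects absolute-agreement single-measure ICC.

    ``data``: n x k matrix of per-rater values (typically triplicate
    means), or n x k x m array of balanced raw replicates to estimate
    single-replicate reliability from the full crossed ANOVA.
    """
    arr = _as_matrix(data)
    if arr.ndim not in (2, 3):
        raise ValueError("expected an n x k matrix or n x k x m array")
    dec, m = _crossed_anova(arr)
    var_s, var_o, var_so, var_e = _agreement_components(dec)
    denom = var_s + var_o + var_so + var_e
    if denom <= 0:
        raise IccUndefinedError("non-positive total variance estimate")
    if m == 1 and dec.ms_error == 0.0 and dec.ms_raters == 0.0:
        est, lo, hi = 1.0, 1.0, 1.0
    else:
        est = var_s / denom
        lo, hi = _agreement_ci(dec, est, alpha)
    return IccResult(
        estimate=float(est),
        ci_low=float(min(lo, est)),
        ci_high=float(max(hi, est)),
        model="twoway_agreement_single",
        alpha=alpha,
        band=classify_icc(float(est)),
        anova=dec,
    )


def icc_twoway_consistency(matrix, alpha: float = 0.05) -> IccResult:
    """Two-way consistency single-measure ICC(C,1) on an n x k matrix.

    Ignores systematic rater offsets: (MS_S - MS_E)/(MS_S + (k-1) MS_E)
    with an exact F interval on ((n-1), (n-1)(k-1)) degrees of freedom.
    """
    arr = _as_matrix(matrix)
    if arr.ndim != 2:
        raise ValueError("expected an n x k matrix")
    dec, _ = _crossed_anova(arr)
    n, k = dec.n_subjects, dec.k_raters
    ms_s, ms_e = dec.ms_subjects, dec.ms_error
    if ms_e == 0.0:
        est, lo, hi = 1.0, 1.0, 1.0
    else:
        est = (ms_s - ms_e) / (ms_s + (k - 1) * ms_e)
        f_obs = ms_s / ms_e
        f_low = f_obs / stats.f.ppf(1 - alpha / 2, dec.df_subjects, dec.df_error)
        f_high = f_obs * stats.f.ppf(1 - alpha / 2, dec.df_error, dec.df_subjects)
        lo = (f_low - 1.0) / (f_low + k - 1.0)
        hi = (f_high - 1.0) / (f_high + k - 1.0)
    return IccResult(
        estimate=float(est),
        ci_low=float(min(lo, est)),
        ci_high=float(max(hi, est)),
        model="twoway_consistency_single",
        alpha=alpha,
        band=classify_icc(float(est)),
        anova=dec,
    )
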