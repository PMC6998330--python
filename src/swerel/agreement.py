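"""Bland-Altman agreement and operator mean comparisons.

Bland-Altman analysis summarises agreement between the two operators by
the mean paired difference (bias), the SD of the differences (n-1
denominator) and the limits of agreement bias +/- 1.96 SD.  The 1.96
multiplier is the conventional large-sample choice; no small-sample t
correction is applied.

Mean comparisons follow the clinical convention of gating the test on a
normality check of the paired differences: Kolmogorov-Smirnov against a
normal with the sample mean and SD by default (the Lilliefors-corrected
variant, which accounts for the estimated parameters, is available and
is the statistically proper choice), then a paired t test if normality
is not rejected, otherwise the Wilcoxon matched-pairs signed-rank test.
Unpaired variants (Student's t / Mann-Whitney) are provided for
between-cohort contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement between paired operators (kPa)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a normality-gated location comparison."""

    test_name: str
    statistic: float
    p_value: float
    normality_p: float


def _paired(op1, op2):
    a = np.asarray(op1, dtype=float)
    b = np.asarray(op2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("operators must be matched 1-D samples of equal length")
    return a, b


def bland_altman(op1, op2) -> BlandAltmanResult:
    """Bias, SD of differences and 1.96-SD limits of agreement."""
    a, b = _paired(op1, op2)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n_pairs=int(a.size),
    )


def bland_altman_frame(op1, op2) -> pd.DataFrame:
    """Plot data (mean of pair, difference) for exact re-plotting."""
    a, b = _paired(op1, op2)
    return pd.DataFrame({"pair_mean_kpa": (a + b) / 2.0, "difference_kpa": a - b})


def bland_altman_plot(op1, op2, ax=None, title: str | None = None):
    """Render the Bland-Altman scatter with bias and LoA lines."""
    import matplotlib.pyplot as plt

    res = bland_altman(op1, op2)
    data = bland_altman_frame(op1, op2)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(data["pair_mean_kpa"], data["difference_kpa"], s=18, alpha=0.8)
    ax.axhline(res.bias, color="k", lw=1)
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("Mean of operators (kPa)")
    ax.set_ylabel("Operator 1 - operator 2 (kPa)")
    if title:
        ax.set_title(title)
    return ax


def normality_p(values, method: str = "ks") -> float:
    """p-value of a normality test on a sample.

    ``ks``: Kolmogorov-Smirnov against a normal with the sample mean
    and SD (conventional in clinical reports, anti-conservative because
    the parameters are estimated).  ``lilliefors``: the corrected
    variant from statsmodels.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("normality test undefined for a constant sample")
    if method == "ks":
        return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        return float(lilliefors(x, dist="norm")[1])
    raise ValueError(f"unknown normality method {method!r}")


def compare_operators(
    op1,
    op2,
    alpha_normality: float = 0.05,
    normality_method: str = "ks",
) -> ComparisonResult:
    """Paired location comparison with a normality gate.

    Differences passing the normality check are compared with a paired
    t test, otherwise with the Wilcoxon matched-pairs signed-rank test.
    """
    a, b = _paired(op1, op2)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: comparison undefined")
    p_norm = normality_p(d, method=normality_method)
    if p_norm >= alpha_normality:
        stat, p = stats.ttest_rel(a, b)
        name = "paired_t"
    else:
        stat, p = stats.wilcoxon(a, b)
        name = "wilcoxon_signed_rank"
    return ComparisonResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        normality_p=p_norm,
    )


def compare_groups(
    x,
    y,
    alpha_normality: float = 0.05,
    normality_method: str = "ks",
) -> ComparisonResult:
    """Unpaired comparison (cross-cohort): Student's t or Mann-Whitney."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    p_norm = min(normality_p(a, normality_method), normality_p(b, normality_method))
    if p_norm >= alpha_normality:
        stat, p = stats.ttest_ind(a, b)
        name = "student_t"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return ComparisonResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        normality_p=p_norm,
    )
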