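"""Bootstrap consistency of the ICC, sample-size planning, view selection.

``bootstrap_icc_probability`` resamples *subjects* (matrix rows) with
replacement, keeping each subject's operator pairing intact, recomputes
the absolute-agreement ICC per resample and reports the fraction of
resamples reaching a threshold (default 0.8, the conventional boundary
of good reliability).  Resamples whose matrix is constant (e.g. a
single distinct subject under perfect agreement) leave the ICC
undefined; they are counted in ``n_degenerate`` and treated as below
threshold, which keeps the probability conservative.

``sample_size_icc`` implements the Walter-Eliasziw-Donner approximation
for the number of subjects needed to show that a reliability
coefficient exceeds a null value rho0 against the alternative rho1:
with theta = rho/(1-rho) and C0 = (1 + k*theta0)/(1 + k*theta1),

    n = 1 + 2 * (z_alpha + z_beta)^2 * k / ((ln C0)^2 * (k - 1)).

An inflation fraction (anticipating uninterpretable acquisitions)
scales the requirement up, rounded to the next integer.

``select_best_view`` picks, per muscle, the probe view with the higher
inter-operator ICC on the training cohort; ties — or overlapping
confidence intervals under the ``ci_overlap`` policy — resolve toward
the longitudinal view, which is the conventional imaging plane for the
muscles studied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .icc import IccResult

logger = logging.getLogger(__name__)

#: Relative tolerance under which a resampled matrix counts as constant.
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class BootstrapResult:
    """Threshold-probability summary of the bootstrap ICC distribution."""

    threshold: float
    n_boot: int
    seed: int
    probability: float
    n_degenerate: int
    icc_quantiles: dict[str, float]


@dataclass(frozen=True)
class SampleSizePlan:
    """Subjects required to demonstrate rho1 against rho0 with k ratings."""

    rho1: float
    rho0: float
    k: int
    alpha: float
    power: float
    sided: str
    n_required: int
    inflation: float
    n_inflated: int


def _agreement_icc_batch(Y: np.ndarray):
    """Vectorised ICC(A,1) over a batch of resampled matrices.

    ``Y`` has shape (B, n, k).  Returns (icc values, degenerate mask);
    degenerate entries (constant matrices) hold NaN.
    """
    B, n, k = Y.shape
    grand = Y.mean(axis=(1, 2), keepdims=True)
    ri = Y.mean(axis=2, keepdims=True)
    cj = Y.mean(axis=1, keepdims=True)
    ss_r = k * ((ri - grand) ** 2).sum(axis=(1, 2))
    ss_c = n * ((cj - grand) ** 2).sum(axis=(1, 2))
    ss_e = ((Y - ri - cj + grand) ** 2).sum(axis=(1, 2))
    scale = np.maximum(np.abs(grand[:, 0, 0]), 1.0) ** 2
    degenerate = (ss_r + ss_c + ss_e) <= _DEGENERATE_RTOL * scale
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = ss_e / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc = np.where(degenerate | (denom <= 0), np.nan, icc)
    return icc, degenerate | (denom <= 0)


def bootstrap_icc_probability(
    matrix,
    threshold: float = 0.8,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Probability that a subject-resampled agreement ICC reaches a threshold.

    Rows of ``matrix`` (n subjects x k operators) are drawn with
    replacement ``n_boot`` times using a seeded generator; the
    absolute-agreement single-measure ICC is recomputed per resample.
    Deterministic given (matrix, seed, n_boot).
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("expected an n x k matrix with n, k >= 2")
    if np.isnan(arr).any():
        raise ValueError("matrix contains NaN")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    icc, degenerate = _agreement_icc_batch(arr[idx])
    ok = ~np.isnan(icc)
    hits = int(np.sum(icc[ok] >= threshold))
    defined = icc[ok]
    qs = (
        {
            "q2.5": float(np.percentile(defined, 2.5)),
            "q25": float(np.percentile(defined, 25)),
            "q50": float(np.percentile(defined, 50)),
            "q75": float(np.percentile(defined, 75)),
            "q97.5": float(np.percentile(defined, 97.5)),
        }
        if defined.size
        else {}
    )
    return BootstrapResult(
        threshold=float(threshold),
        n_boot=int(n_boot),
        seed=int(seed),
        probability=hits / n_boot,
        n_degenerate=int(degenerate.sum()),
        icc_quantiles=qs,
    )


def inflate_sample_size(n_required: int, inflation: float) -> int:
    """Inflate a subject requirement for anticipated unusable measures."""
    if inflation < 0:
        raise ValueError("inflation must be >= 0")
    return math.ceil(n_required * (1.0 + inflation))


def sample_size_icc(
    rho1: float,
    rho0: float,
    k: int = 2,
    alpha: float = 0.05,
    power: float = 0.80,
    sided: str = "one",
    inflation: float = 0.0,
) -> SampleSizePlan:
    """Walter-Eliasziw-Donner sample size for an ICC reliability study."""
    if not 0 <= rho0 < rho1 < 1:
        raise ValueError("need 0 <= rho0 < rho1 < 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    z_a = stats.norm.ppf(1 - alpha) if sided == "one" else stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    theta0 = rho0 / (1 - rho0)
    theta1 = rho1 / (1 - rho1)
    c0 = (1 + k * theta0) / (1 + k * theta1)
    n_exact = 1 + 2 * (z_a + z_b) ** 2 * k / (math.log(c0) ** 2 * (k - 1))
    n_required = max(2, math.ceil(n_exact))
    return SampleSizePlan(
        rho1=rho1,
        rho0=rho0,
        k=k,
        alpha=alpha,
        power=power,
        sided=sided,
        n_required=n_required,
        inflation=inflation,
        n_inflated=inflate_sample_size(n_required, inflation),
    )


def select_best_view(
    training_results: Mapping[str, Mapping[str, IccResult]],
    tie_policy: str = "prefer_longitudinal",
) -> dict[str, str]:
    """Per muscle, the view with the higher inter-operator ICC.

    ``training_results`` maps muscle -> view -> IccResult and must hold
    both views per muscle.  Under ``prefer_longitudinal`` only exact
    ties resolve toward the longitudinal view; under ``ci_overlap``
    overlapping confidence intervals are treated as a tie as well.
    """
    if tie_policy not in ("prefer_longitudinal", "ci_overlap"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    selected: dict[str, str] = {}
    for muscle, by_view in training_results.items():
        try:
            lon = by_view["longitudinal"]
            tra = by_view["transverse"]
        except KeyError as exc:
            raise ValueError(f"{muscle}: missing {exc.args[0]} view result") from exc
        margin = lon.estimate - tra.estimate
        if tie_policy == "ci_overlap":
            overlap = lon.ci_low <= tra.ci_high and tra.ci_low <= lon.ci_high
            choice = "longitudinal" if (overlap or margin >= 0) else "transverse"
            reason = "ci_overlap tie -> longitudinal" if overlap else "higher estimate"
        else:
            choice = "longitudinal" if margin >= 0 else "transverse"
            reason = "tie -> longitudinal" if margin == 0 else "higher estimate"
        logger.info(
            "%s: selected %s view (%s; longitudinal %.3f vs transverse %.3f)",
            muscle,
            choice,
            reason,
            lon.estimate,
            tra.estimate,
        )
        selected[muscle] = choice
    return selected
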