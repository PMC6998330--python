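import numpy as np
import pytest

from _oracles import icc_agreement_single
from swerel.design import (
    bootstrap_icc_probability,
    inflate_sample_size,
    sample_size_icc,
    select_best_view,
)
from swerel.icc import AnovaDecomposition, IccResult, classify_icc
from swerel.records import operator_matrix
from swerel.simulate import CohortSpec, VarianceComponents, generate_cohort


def make_icc(estimate, ci_low=None, ci_high=None):
    ci_low = estimate - 0.2 if ci_low is None else ci_low
    ci_high = min(1.0, estimate + 0.1) if ci_high is None else ci_high
    anova = AnovaDecomposition(
        n_subjects=16, k_raters=2, ms_subjects=1.0, df_subjects=15
    )
    return IccResult(
        estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        model="twoway_agreement_single",
        alpha=0.05,
        band=classify_icc(estimate),
        anova=anova,
    )


class TestBootstrap:
    def test_perfect_agreement_probability_one(self):
        col = np.linspace(10, 55, 10)
        mat = np.column_stack([col, col])
        res = bootstrap_icc_probability(mat, threshold=0.8, n_boot=5000, seed=1)
        assert res.probability == 1.0
        assert res.n_degenerate == 0

    def test_deterministic_given_seed(self, rng):
        mat = rng.normal(20, 4, (8, 2))
        a = bootstrap_icc_probability(mat, n_boot=2000, seed=5)
        b = bootstrap_icc_probability(mat, n_boot=2000, seed=5)
        assert a == b

    def test_matches_independent_reimplementation(self, rng):
        """Same resample indices, ICC recomputed by an independent
        loop-based implementation: probabilities agree exactly."""
        col = rng.normal(20, 4, 6)
        mat = np.column_stack([col, col + rng.normal(0.5, 1.5, 6)])
        seed, n_boot, thr = 17, 2000, 0.8
        res = bootstrap_icc_probability(mat, threshold=thr, n_boot=n_boot, seed=seed)
        idx = np.random.default_rng(seed).integers(0, 6, size=(n_boot, 6))
        hits = degenerate = 0
        for row in idx:
            icc = icc_agreement_single(mat[row].tolist())
            if icc is None:
                degenerate += 1
            elif icc >= thr:
                hits += 1
        assert res.probability == hits / n_boot
        assert res.n_degenerate == degenerate

    def test_vacuous_threshold_is_certain(self, rng):
        # strong subject signal: every resampled ICC is defined and >= -1
        col = rng.normal(20, 6, 8)
        mat = np.column_stack([col, col + rng.normal(0, 0.5, 8)])
        res = bootstrap_icc_probability(mat, threshold=-1.0, n_boot=2000, seed=2)
        assert res.probability == 1.0

    def test_constant_data_all_degenerate(self):
        mat = np.full((6, 2), 13.0)
        res = bootstrap_icc_probability(mat, n_boot=500, seed=3)
        assert res.n_degenerate == 500
        assert res.probability == 0.0

    def test_icu_like_cohorts_mostly_exceed_threshold(self):
        """Cohorts simulated at a true agreement ICC of 0.92 should give
        bootstrap probabilities of reaching 0.8 well above one half, with
        visible dataset-to-dataset spread."""
        vc = VarianceComponents(13.7, 11.5, 0.2, 0.3, 0.5)
        probs = []
        for seed in range(40):
            spec = CohortSpec(
                cohort="icu",
                n_subjects=12,
                muscles=("diaphragm",),
                views=("longitudinal",),
                components={("diaphragm", "longitudinal"): vc},
                seed=seed,
            )
            _, mat = operator_matrix(
                generate_cohort(spec), "diaphragm", "longitudinal"
            )
            probs.append(
                bootstrap_icc_probability(mat, n_boot=2000, seed=seed).probability
            )
        assert 0.5 < np.median(probs) <= 1.0
        assert np.std(probs) > 0.0

    def test_invalid_inputs_rejected(self, rng):
        mat = rng.normal(20, 4, (6, 2))
        with pytest.raises(ValueError):
            bootstrap_icc_probability(mat, n_boot=0)
        with pytest.raises(ValueError):
            bootstrap_icc_probability(mat[:1])


class TestSampleSize:
    def test_walter_eliasziw_donner_worked_example(self):
        plan = sample_size_icc(0.8, 0.6, k=2, alpha=0.05, power=0.8, sided="one")
        assert plan.n_required == 39

    def test_inflation_arithmetic(self):
        assert inflate_sample_size(56, 0.25) == 70
        plan = sample_size_icc(0.8, 0.6, k=2, inflation=0.25)
        assert plan.n_inflated == int(np.ceil(plan.n_required * 1.25))

    def test_shrinking_effect_size_inflates_n(self):
        wide = sample_size_icc(0.8, 0.4).n_required
        narrow = sample_size_icc(0.8, 0.7).n_required
        tiny = sample_size_icc(0.8, 0.78).n_required
        assert wide < narrow < tiny

    def test_more_ratings_never_need_more_subjects(self):
        ns = [sample_size_icc(0.8, 0.6, k=k).n_required for k in (2, 3, 5, 10)]
        assert all(b <= a for a, b in zip(ns, ns[1:]))

    def test_invalid_rhos_rejected(self):
        with pytest.raises(ValueError):
            sample_size_icc(0.6, 0.8)
        with pytest.raises(ValueError):
            sample_size_icc(0.8, 0.8)


class TestSelectBestView:
    def test_training_pattern_selects_longitudinal(self):
        results = {
            "diaphragm": {
                "longitudinal": make_icc(0.83, 0.50, 0.94),
                "transverse": make_icc(0.3, -0.86, 0.75),
            },
            "biceps_brachii": {
                "longitudinal": make_icc(0.88, 0.67, 0.96),
                "transverse": make_icc(0.39, -0.29, 0.76),
            },
        }
        assert select_best_view(results) == {
            "diaphragm": "longitudinal",
            "biceps_brachii": "longitudinal",
        }

    def test_higher_transverse_wins_by_default_policy(self):
        results = {
            "rectus_femoris": {
                "longitudinal": make_icc(0.76, 0.34, 0.91),
                "transverse": make_icc(0.82, 0.50, 0.94),
            }
        }
        assert select_best_view(results) == {"rectus_femoris": "transverse"}

    def test_exact_tie_prefers_longitudinal(self):
        results = {
            "diaphragm": {
                "longitudinal": make_icc(0.8),
                "transverse": make_icc(0.8),
            }
        }
        assert select_best_view(results)["diaphragm"] == "longitudinal"

    def test_ci_overlap_policy_treats_overlap_as_tie(self):
        results = {
            "rectus_femoris": {
                "longitudinal": make_icc(0.76, 0.34, 0.91),
                "transverse": make_icc(0.82, 0.50, 0.94),
            }
        }
        assert select_best_view(results, tie_policy="ci_overlap") == {
            "rectus_femoris": "longitudinal"
        }
        separated = {
            "rectus_femoris": {
                "longitudinal": make_icc(0.3, 0.1, 0.45),
                "transverse": make_icc(0.9, 0.8, 0.97),
            }
        }
        assert select_best_view(separated, tie_policy="ci_overlap") == {
            "rectus_femoris": "transverse"
        }

    def test_missing_view_rejected(self):
        with pytest.raises(ValueError):
            select_best_view({"diaphragm": {"longitudinal": make_icc(0.8)}})
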