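import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import (
    icc_agreement_single,
    oneway_mean_squares,
    replicated_mean_squares,
    twoway_mean_squares,
)
from swerel.icc import (
    IccUndefinedError,
    classify_icc,
    icc_oneway,
    icc_twoway_agreement,
    icc_twoway_consistency,
)

TOY_3X2 = np.array([[10.0, 12.0], [20.0, 22.0], [30.0, 32.0]])


def random_matrix(seed, n=10, k=2, sd_subject=3.0, sd_noise=1.0, offset=0.0):
    rng = np.random.default_rng(seed)
    subj = rng.normal(20, sd_subject, n)[:, None]
    return subj + np.arange(k) * offset + rng.normal(0, sd_noise, (n, k))


class TestClassification:
    @pytest.mark.parametrize(
        "estimate, band",
        [
            (0.83, "good"),
            (0.3, "poor"),
            (0.90, "excellent"),
            (0.4999, "poor"),
            (0.50, "moderate"),
            (0.75, "good"),
            (-0.4, "poor"),
            (1.0, "excellent"),
        ],
    )
    def test_bands(self, estimate, band):
        assert classify_icc(estimate) == band


class TestOneWay:
    def test_worked_3x2_example(self):
        res = icc_oneway(TOY_3X2)
        assert res.anova.ms_subjects == pytest.approx(200.0)
        assert res.anova.ms_within == pytest.approx(2.0)
        assert res.estimate == pytest.approx(198.0 / 202.0)

    def test_identical_replicates_give_one(self):
        mat = np.repeat([[10.0], [20.0], [30.0]], 3, axis=1)
        res = icc_oneway(mat)
        assert res.estimate == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_null_simulation_centres_on_zero(self):
        """With no subject effect the estimate averages near 0 and the CI
        covers 0 at close to the nominal rate."""
        rng = np.random.default_rng(99)
        estimates, covered = [], 0
        reps = 500
        for _ in range(reps):
            mat = rng.normal(0, 1, (30, 3))
            res = icc_oneway(mat)
            estimates.append(res.estimate)
            covered += res.ci_low <= 0 <= res.ci_high
        assert abs(np.mean(estimates)) < 0.02
        assert covered / reps > 0.90

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_squares_match_bruteforce(self, seed):
        mat = random_matrix(seed, n=8, k=3)
        res = icc_oneway(mat)
        msb, msw = oneway_mean_squares(mat.tolist())
        assert res.anova.ms_subjects == pytest.approx(msb, rel=1e-10)
        assert res.anova.ms_within == pytest.approx(msw, rel=1e-10)

    def test_unbalanced_replicates_handled(self):
        mat = np.array([[10.0, 12.0, 11.0], [20.0, 22.0, np.nan], [30.0, 32.0, 31.0]])
        res = icc_oneway(mat)
        assert 0 < res.estimate <= 1

    def test_constant_matrix_undefined(self):
        with pytest.raises(IccUndefinedError):
            icc_oneway(np.full((4, 3), 7.0))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway(np.array([[1.0, 2.0]]))


class TestTwoWayAgreement:
    def test_perfect_agreement_gives_one(self):
        col = np.array([10.0, 20.0, 30.0, 40.0])
        res = icc_twoway_agreement(np.column_stack([col, col]))
        assert res.estimate == 1.0

    def test_operator_offset_lowers_agreement_below_consistency(self):
        mat = np.column_stack([[10.0, 20, 30, 40], [15.0, 25, 35, 45]])
        agr = icc_twoway_agreement(mat).estimate
        con = icc_twoway_consistency(mat).estimate
        assert agr < con
        # oracle on the same ANOVA
        assert agr == pytest.approx(icc_agreement_single(mat.tolist()), rel=1e-10)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_mean_squares_match_bruteforce(self, seed):
        mat = random_matrix(seed, n=12, k=2, offset=1.0)
        res = icc_twoway_agreement(mat)
        ms_s, ms_r, ms_e = twoway_mean_squares(mat.tolist())
        assert res.anova.ms_subjects == pytest.approx(ms_s, rel=1e-10)
        assert res.anova.ms_raters == pytest.approx(ms_r, rel=1e-10)
        assert res.anova.ms_error == pytest.approx(ms_e, rel=1e-10)
        assert res.estimate == pytest.approx(icc_agreement_single(mat.tolist()), rel=1e-10)

    def test_monotone_degradation_with_growing_offset(self):
        base = random_matrix(7, n=12, k=2)
        estimates = []
        for offset in (0.0, 1.0, 2.0, 4.0, 8.0):
            mat = base.copy()
            mat[:, 1] += offset
            estimates.append(icc_twoway_agreement(mat).estimate)
        assert all(b <= a + 1e-12 for a, b in zip(estimates, estimates[1:]))

    def test_replicated_mode_matches_bruteforce_components(self):
        rng = np.random.default_rng(21)
        cube = (
            20
            + rng.normal(0, 3, 10)[:, None, None]
            + rng.normal(0, 0.5, 2)[None, :, None]
            + rng.normal(0, 0.7, (10, 2))[:, :, None]
            + rng.normal(0, 1.0, (10, 2, 3))
        )
        res = icc_twoway_agreement(cube)
        ms_s, ms_o, ms_so, ms_e = replicated_mean_squares(cube.tolist())
        assert res.anova.ms_subjects == pytest.approx(ms_s, rel=1e-10)
        assert res.anova.ms_raters == pytest.approx(ms_o, rel=1e-10)
        assert res.anova.ms_interaction == pytest.approx(ms_so, rel=1e-10)
        assert res.anova.ms_error == pytest.approx(ms_e, rel=1e-10)
        n, k, m = cube.shape
        vs = (ms_s - ms_so) / (k * m)
        vo = (ms_o - ms_so) / (n * m)
        vso = (ms_so - ms_e) / m
        expected = vs / (vs + vo + vso + ms_e)
        assert res.estimate == pytest.approx(expected, rel=1e-10)

    def test_constant_matrix_undefined(self):
        with pytest.raises(IccUndefinedError):
            icc_twoway_agreement(np.full((5, 2), 13.0))

    def test_nan_rejected(self):
        mat = random_matrix(1)
        mat[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_twoway_agreement(mat)


class TestConfidenceIntervals:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_ci_brackets_estimate(self, seed):
        mat = random_matrix(seed, n=10, k=2, offset=0.8)
        for fn in (icc_oneway, icc_twoway_agreement, icc_twoway_consistency):
            res = fn(mat)
            assert res.ci_low <= res.estimate <= res.ci_high

    def test_wider_alpha_narrows_interval(self):
        mat = random_matrix(15, n=12, k=2)
        narrow = icc_twoway_agreement(mat, alpha=0.10)
        wide = icc_twoway_agreement(mat, alpha=0.01)
        assert wide.ci_low <= narrow.ci_low
        assert narrow.ci_high <= wide.ci_high

    @pytest.mark.parametrize("seed,k", [(42, 2), (43, 3), (44, 2)])
    def test_matches_pingouin(self, seed, k):
        """Estimates agree to 1e-10 and CI bounds to pingouin's printed
        precision for ICC(1), ICC(A,1) and ICC(C,1)."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        mat = random_matrix(seed, n=14, k=k, offset=1.1)
        n = mat.shape[0]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": mat.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        ours = {
            "ICC(1,1)": icc_oneway(mat),
            "ICC(A,1)": icc_twoway_agreement(mat),
            "ICC(C,1)": icc_twoway_consistency(mat),
        }
        for typ, res in ours.items():
            assert res.estimate == pytest.approx(ref.loc[typ, "ICC"], abs=1e-10)
            lo, hi = ref.loc[typ, "CI95"]
            assert res.ci_low == pytest.approx(lo, abs=6e-3)
            assert res.ci_high == pytest.approx(hi, abs=6e-3)


class TestAffineInvariance:
    @given(
        seed=st.integers(0, 50),
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_common_affine_transform_preserves_icc(self, seed, a, b):
        mat = random_matrix(seed, n=8, k=2, offset=0.5)
        for fn in (icc_oneway, icc_twoway_agreement, icc_twoway_consistency):
            before = fn(mat).estimate
            after = fn(a * mat + b).estimate
            assert after == pytest.approx(before, rel=1e-8, abs=1e-10)
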