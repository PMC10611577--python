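"""Inferential layer: exact identities, printed-value cross-checks, calibration."""

import numpy as np
import pytest

from mbnf import stats as st
from mbnf import synth
from mbnf.errors import DegenerateDataError


class TestPearson:
    def test_t_conversion_identity(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        res = st.pearson(x, y)
        expected_t = res.r * np.sqrt(res.n - 2) / np.sqrt(1 - res.r**2)
        assert res.t == pytest.approx(expected_t, abs=1e-12)
        assert res.df == res.n - 2

    def test_r_069_n9_matches_reported_t_and_p(self):
        """A correlation of 0.69 with 9 subjects converts to t = 2.52 and
        two-tailed p = 0.039 — the performance/mindfulness-change pairing."""
        # construct a 9-point sample with sample r = 0.69 exactly
        rng = np.random.default_rng(5)
        x = rng.standard_normal(9)
        e = rng.standard_normal(9)
        x = (x - x.mean()) / x.std()
        e -= e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        r_target = 0.69
        y = r_target * x + np.sqrt(1 - r_target**2) * e
        res = st.pearson(x, y)
        assert res.r == pytest.approx(0.69, abs=1e-10)
        assert res.t == pytest.approx(2.52, abs=0.01)
        assert res.p == pytest.approx(0.039, abs=0.001)

    def test_one_tailed_is_half_two_tailed_in_effect_direction(self, rng):
        x = rng.standard_normal(20)
        y = x + rng.standard_normal(20)
        res = st.pearson(x, y)
        assert res.p_one_tailed == pytest.approx(res.p_two_tailed / 2)

    def test_perfect_linearity_reported_degenerate(self):
        x = np.arange(10.0)
        res = st.pearson(x, 2 * x + 1)
        assert res.degenerate
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            st.pearson(np.ones(5), np.arange(5.0))

    def test_type_one_error_calibrated_at_n9(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            x = rng.standard_normal(9)
            y = rng.standard_normal(9)
            if st.pearson(x, y).p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.012)


class TestTTests:
    def test_identical_vectors_t_zero_p_one(self):
        res = st.paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_degenerate_guard(self):
        res = st.paired_t([2.0, 3, 4], [1.0, 2, 3])
        assert res.degenerate and np.isinf(res.t)

    def test_t190_df8_tail_probabilities(self):
        """t(8) = 1.90: one-tailed p = 0.047, two-tailed p = 0.094 — the
        state-mindfulness pre/post comparison sits exactly on this boundary."""
        from scipy import stats as sps

        assert sps.t.sf(1.90, 8) == pytest.approx(0.047, abs=0.0005)
        rng = np.random.default_rng(3)
        d = rng.standard_normal(9)
        d = (d - d.mean()) / d.std(ddof=1)
        d += 1.90 / np.sqrt(9)  # sample t is now exactly 1.90
        res = st.one_sample_t(d, 0.0, "greater")
        assert res.t == pytest.approx(1.90, abs=1e-9)
        assert res.p == pytest.approx(0.047, abs=0.0005)
        res2 = st.one_sample_t(d, 0.0, "two-sided")
        assert res2.p == pytest.approx(0.094, abs=0.001)

    def test_mean_at_null_gives_t_zero(self):
        res = st.one_sample_t([0.4, 0.6, 0.5, 0.45, 0.55], 0.5)
        assert res.t == 0.0


class TestICC:
    def test_identical_sessions_icc_one(self):
        res = st.icc_absolute_agreement(np.arange(10.0), np.arange(10.0))
        assert res.icc == pytest.approx(1.0)

    def test_independent_redraw_near_zero(self):
        rng = np.random.default_rng(4)
        res = st.icc_absolute_agreement(rng.standard_normal(400),
                                        rng.standard_normal(400))
        assert abs(res.icc) < 0.12

    def test_variance_ratio_9_to_1_gives_point_nine(self):
        rng = np.random.default_rng(5)
        traits = 3.0 * rng.standard_normal(800)
        s1 = traits + rng.standard_normal(800)
        s2 = traits + rng.standard_normal(800)
        res = st.icc_absolute_agreement(s1, s2)
        assert res.icc == pytest.approx(0.9, abs=0.03)
        assert res.p < 0.01

    def test_constant_input_degenerate(self):
        res = st.icc_absolute_agreement(np.ones(5), np.ones(5))
        assert res.degenerate


class TestStandardizedBetas:
    def test_printed_mediation_table_reproduced(self):
        """From the printed pairwise correlations (r_xy = 0.69, r_xm = -0.67,
        r_my = -0.88, n = 9) the two-predictor fit gives beta_b = -0.76 and
        beta_c' = 0.18, with t_c' = 0.73."""
        out = st.standardized_betas_from_corr(0.69, -0.67, -0.88, 9)
        assert out["beta_b"] == pytest.approx(-0.76, abs=0.005)
        assert out["beta_c_prime"] == pytest.approx(0.18, abs=0.005)
        assert out["t_c_prime"] == pytest.approx(0.73, abs=0.01)
        assert out["t_b"] == pytest.approx(-3.03, abs=0.01)

    def test_orthogonal_predictors_reduce_to_simple_correlations(self):
        out = st.standardized_betas_from_corr(0.4, 0.0, 0.5, 20)
        assert out["beta_b"] == pytest.approx(0.5)
        assert out["beta_c_prime"] == pytest.approx(0.4)

    @pytest.mark.parametrize("r_xy,r_xm,r_my", [(0.69, -0.67, -0.88),
                                                (0.3, 0.5, 0.4),
                                                (-0.2, 0.6, -0.5)])
    def test_decomposition_identity(self, r_xy, r_xm, r_my):
        out = st.standardized_betas_from_corr(r_xy, r_xm, r_my, 9)
        # beta_a = r_xm in the simple standardized regression of M on X
        assert r_xm * out["beta_b"] + out["beta_c_prime"] == pytest.approx(r_xy, abs=1e-12)

    def test_collinear_predictors_rejected(self):
        with pytest.raises(ValueError):
            st.standardized_betas_from_corr(0.5, 1.0, 0.5, 9)


class TestSobel:
    def test_printed_coefficients_give_z_189(self):
        """Recomputing from the printed unstandardized paths (a = -0.12 with
        t = -2.39, b = -141.75 with t = -3.07) gives z = 1.89, matching the
        printed 1.88 within last-digit rounding, with p ~ 0.06."""
        se_a = 0.12 / 2.39
        se_b = 141.75 / 3.07
        z, p = st.sobel_test(-0.12, se_a, -141.75, se_b)
        assert z == pytest.approx(1.89, abs=0.005)
        assert p == pytest.approx(0.060, abs=0.002)

    def test_sign_follows_product_of_paths(self):
        z_pos, _ = st.sobel_test(-1.0, 0.2, -1.0, 0.2)
        z_neg, _ = st.sobel_test(-1.0, 0.2, 1.0, 0.2)
        assert z_pos > 0 > z_neg


class TestMediate:
    def test_noiseless_outcome_chain_fully_mediated(self):
        # y is an exact multiple of m (m itself carries noise so that x and
        # m are not collinear): the direct path c' must vanish identically
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        m = -0.5 * x + 0.3 * rng.standard_normal(30)
        y = 2.0 * m
        res = st.mediate(x, m, y)
        assert res.path_c_prime.b == pytest.approx(0.0, abs=1e-10)
        assert np.sign(res.sobel_z) == np.sign(-0.5 * 2.0)

    def test_standardized_decomposition_identity(self, rng):
        x = rng.standard_normal(25)
        m = 0.4 * x + rng.standard_normal(25)
        y = -0.3 * m + 0.2 * x + rng.standard_normal(25)
        res = st.mediate(x, m, y)
        lhs = res.path_c.beta
        rhs = res.path_a.beta * res.path_b.beta + res.path_c_prime.beta
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_large_cohort_recovers_generative_paths(self):
        coh = synth.simulate_behavior_cohort(5000, -0.7, -0.8, 0.0, seed=1)
        res = st.mediate(coh.x, coh.m, coh.y)
        assert res.path_a.beta == pytest.approx(-0.7, abs=0.05)
        assert res.path_b.beta == pytest.approx(-0.8, abs=0.05)
        assert res.path_c_prime.beta == pytest.approx(0.0, abs=0.05)

    def test_affine_rescaling_leaves_standardized_fields_unchanged(self, rng):
        x = rng.standard_normal(15)
        m = 0.5 * x + rng.standard_normal(15)
        y = -0.4 * m + rng.standard_normal(15)
        r1 = st.mediate(x, m, y)
        r2 = st.mediate(3 * x - 1, 0.01 * m + 5, 100 * y + 3)
        for p1, p2 in [(r1.path_a, r2.path_a), (r1.path_b, r2.path_b),
                       (r1.path_c, r2.path_c), (r1.path_c_prime, r2.path_c_prime)]:
            assert p1.beta == pytest.approx(p2.beta, abs=1e-9)
            assert p1.t == pytest.approx(p2.t, abs=1e-9)
        assert r1.sobel_z == pytest.approx(r2.sobel_z, abs=1e-9)

    def test_degenerate_and_collinear_inputs_rejected(self, rng):
        x = rng.standard_normal(10)
        with pytest.raises(DegenerateDataError):
            st.mediate(x, np.ones(10), x)
        with pytest.raises(DegenerateDataError):
            st.mediate(x, 2 * x, x + rng.standard_normal(10))
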