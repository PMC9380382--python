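import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ncctrends import (
    control_estimate_period2,
    power_pooled,
    rho,
    theta2_weighted,
    variance_reduction,
    weights,
)

counts = st.integers(1, 200)


def _implied_weights(n):
    """Brute-force oracle: recover the cell-mean weights of the theta2
    estimate directly from the least-squares solution of the all-arm step
    model (hat-row of the theta2 coordinate, summed within each cell)."""
    arm = np.concatenate([np.repeat([0, 1], n[:2, 0]), np.repeat([0, 1, 2], n[:, 1])])
    period = np.concatenate([np.ones(n[:2, 0].sum(), int), np.full(n[:, 1].sum(), 2)])
    X = np.column_stack([
        np.ones(arm.size), arm == 1, arm == 2, period == 2,
    ]).astype(float)
    hat = np.linalg.solve(X.T @ X, np.eye(4)[2]) @ X.T  # theta2 row
    w = np.zeros((3, 2))
    for k in range(3):
        for s in (1, 2):
            sel = (arm == k) & (period == s)
            w[k, s - 1] = hat[sel].sum()
    return w


class TestRho:
    def test_equal_cells_of_125(self):
        assert rho(125, 125, 125, 125) == pytest.approx(0.25)

    def test_unequal_cells_closed_form(self):
        assert rho(100, 50, 200, 25) == pytest.approx(1 / 15)

    def test_limits(self):
        assert rho(125, 125, 10**9, 125) < 1e-5
        assert rho(10**9, 10**9, 125, 10**9) > 1 - 1e-5

    @given(n01=counts, n02=counts)
    def test_equal_randomisation_special_case(self, n01, n02):
        # n01 = n11, n02 = n12: reduction is half the non-concurrent share
        assert rho(n01, n01, n02, n02) == pytest.approx(0.5 * n01 / (n01 + n02))
        assert rho(n01, n01, n02, n02) < 0.5

    @given(n01=counts, n11=counts, n02=counts, n12=counts)
    def test_monotone_in_each_count(self, n01, n11, n02, n12):
        base = rho(n01, n11, n02, n12)
        assert rho(n01 + 1, n11, n02, n12) > base
        assert rho(n01, n11 + 1, n02, n12) > base
        assert rho(n01, n11, n02, n12 + 1) > base
        assert rho(n01, n11, n02 + 1, n12) < base
        assert 0 < base < 1

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            rho(0, 125, 125, 125)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(1, 30, size=(3, 2))
            n[2, 0] = 0
            n[2, 1] = max(n[2, 1], 1)
            np.testing.assert_allclose(_implied_weights(n), weights(n).w, atol=1e-10)


class TestWeights:
    def test_equal_cells_matrix(self, two_period_design):
        wm = weights(two_period_design)
        np.testing.assert_allclose(
            wm.w, [[-0.25, -0.75], [0.25, -0.25], [0.0, 1.0]])
        assert wm.rho == pytest.approx(0.25)

    def test_rho_zero_limit_is_separate_comparison(self):
        wm = weights([[5, 10**9], [5, 5], [0, 20]])
        np.testing.assert_allclose(wm.w, [[0, -1], [0, 0], [0, 1]], atol=1e-8)

    @given(n01=counts, n11=counts, n02=counts, n12=counts, n22=counts)
    def test_invariants(self, n01, n11, n02, n12, n22):
        wm = weights([[n01, n02], [n11, n12], [0, n22]])
        assert wm.w.sum() == pytest.approx(0.0)
        assert wm.w[2, 1] == 1.0 and wm.w[2, 0] == 0.0

    def test_late_arm_recruiting_early_rejected(self):
        with pytest.raises(ValueError):
            weights([[5, 5], [5, 5], [3, 5]])


class TestTheta2Weighted:
    def test_all_means_equal_gives_zero(self, two_period_design):
        ybar = np.full((3, 2), 1.7)
        assert theta2_weighted(ybar, two_period_design.n) == pytest.approx(0.0)

    def test_equal_trends_recover_true_effect(self, two_period_design):
        # cell means under an equal 0.1 step trend and theta2 = 0.25
        ybar = np.array([[0.0, 0.1], [0.25, 0.35], [np.nan, 0.35]])
        assert theta2_weighted(ybar, two_period_design.n) == pytest.approx(0.25)

    def test_missing_required_cell_rejected(self, two_period_design):
        ybar = np.array([[0.0, np.nan], [0.25, 0.35], [np.nan, 0.35]])
        with pytest.raises(ValueError, match="missing"):
            theta2_weighted(ybar, two_period_design.n)


class TestControlEstimate:
    def test_shrinkage_example(self, two_period_design):
        ybar = np.array([[0.0, 0.1], [0.25, 0.35], [np.nan, 0.35]])
        # 0.75 * 0.1 + 0.25 * (0 + 0.35 - 0.25)
        assert control_estimate_period2(ybar, two_period_design.n) == pytest.approx(0.1)

    def test_rho_zero_reduces_to_concurrent_mean(self):
        n = [[5, 10**9], [5, 5], [0, 20]]
        ybar = np.array([[0.3, 0.9], [0.1, 0.8], [np.nan, 0.7]])
        assert control_estimate_period2(ybar, n) == pytest.approx(0.9, abs=1e-7)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.integers(1, 50))
    def test_identity_with_theta2(self, n01, n11, n02, n12, n22):
        n = [[n01, n02], [n11, n12], [0, n22]]
        rng = np.random.default_rng(n01 * 7 + n02)
        ybar = rng.normal(size=(3, 2))
        assert theta2_weighted(ybar, n) == pytest.approx(
            ybar[2, 1] - control_estimate_period2(ybar, n))


class TestVarianceReduction:
    def test_equal_cells_is_25_percent(self):
        assert variance_reduction(125, 125, 125, 125) == pytest.approx(0.25)

    def test_bounded_below_half_under_equal_randomisation(self):
        assert variance_reduction(10**7, 10**7, 125, 10**7 ) < 1  # general bound
        assert variance_reduction(10**7, 10**7, 125, 125) < 0.5
        # approaches 1/2 from below as non-concurrent controls grow
        assert variance_reduction(10**7, 10**7, 125, 125) > 0.4999


class TestPower:
    def test_continuous_calibration_80_percent(self):
        p = power_pooled("continuous", 250, delta=0.25, sigma=1.0, alpha=0.025)
        assert p == pytest.approx(0.80, abs=0.01)

    def test_binary_calibration_80_percent_both_variants(self):
        for pooled_variance in (False, True):
            p = power_pooled("binary", 250, p0=0.7, odds_ratio=1.8, alpha=0.025,
                             pooled_variance=pooled_variance)
            assert p == pytest.approx(0.80, abs=0.01)

    def test_null_effect_gives_alpha(self):
        assert power_pooled("continuous", 100, delta=0.0, sigma=1.0,
                            alpha=0.025) == pytest.approx(0.025)
        assert power_pooled("binary", 100, p0=0.7, odds_ratio=1.0,
                            alpha=0.025) == pytest.approx(0.025)

    def test_unequal_group_sizes(self):
        small = power_pooled("continuous", (50, 250), delta=0.25, sigma=1.0)
        big = power_pooled("continuous", (250, 250), delta=0.25, sigma=1.0)
        assert small < big

    @pytest.mark.parametrize("kwargs", [
        dict(delta=0.2, sigma=-1.0),
        dict(p0=1.4, odds_ratio=2.0),
        dict(p0=0.7, odds_ratio=-2.0),
    ])
    def test_invalid_inputs(self, kwargs):
        endpoint = "continuous" if "sigma" in kwargs else "binary"
        with pytest.raises(ValueError):
            power_pooled(endpoint, 100, **kwargs)
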