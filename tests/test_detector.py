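"""Unit and property tests for the greatest-root change process."""

import math

import numpy as np
import pytest
import scipy.linalg

from rmtcpt import (
    ChangeProcess,
    TimeSeriesMatrix,
    binary_segmentation,
    change_process,
    compute_scatter_pair,
    detect_change_point,
    greatest_root,
    iter_scatter_pairs,
    standardized_logit,
    tw_centering,
)
from rmtcpt.detector import ScatterPair, _argmax_smallest
from rmtcpt.permutation import PermutationConfig


# ---------------------------------------------------------------------------
# scatter pairs
# ---------------------------------------------------------------------------


class TestScatterPair:
    def test_zero_series_gives_zero_scatter(self):
        y = TimeSeriesMatrix(np.zeros((2, 12)))
        pair = compute_scatter_pair(y, 5)
        assert np.all(pair.a == 0) and np.all(pair.b == 0)

    def test_univariate_hand_sum(self):
        y = TimeSeriesMatrix(np.array([[1.0, -1.0, 1.0, -1.0]]))
        pair = compute_scatter_pair(y, 2)
        assert pair.mean_left == pytest.approx(0.0)
        assert pair.mean_right == pytest.approx(0.0)
        assert pair.a == pytest.approx(np.array([[2.0]]))
        assert pair.b == pytest.approx(np.array([[2.0]]))

    def test_matches_two_pass_summation_oracle(self, rng):
        y = TimeSeriesMatrix(rng.standard_normal((5, 40)))
        pair = compute_scatter_pair(y, 17)
        # independent elementwise two-pass summation
        v = y.values
        ml = v[:, :17].sum(axis=1) / 17
        mr = v[:, 17:].sum(axis=1) / 23
        a = sum(np.outer(v[:, u] - ml, v[:, u] - ml) for u in range(17))
        b = sum(np.outer(v[:, u] - mr, v[:, u] - mr) for u in range(17, 40))
        np.testing.assert_allclose(pair.a, a, atol=1e-10)
        np.testing.assert_allclose(pair.b, b, atol=1e-10)

    def test_additivity_of_pooled_scatter(self, rng):
        y = TimeSeriesMatrix(rng.standard_normal((4, 30)))
        pair = compute_scatter_pair(y, 11)
        v = y.values
        pooled = np.zeros((4, 4))
        for lo, hi, m in ((0, 11, pair.mean_left), (11, 30, pair.mean_right)):
            c = v[:, lo:hi] - m[:, None]
            pooled += c @ c.T
        np.testing.assert_allclose(pair.a + pair.b, pooled, atol=1e-10)

    def test_split_out_of_range(self):
        y = TimeSeriesMatrix(np.random.default_rng(0).standard_normal((2, 10)))
        with pytest.raises(ValueError, match="split index"):
            compute_scatter_pair(y, 0)
        with pytest.raises(ValueError, match="split index"):
            compute_scatter_pair(y, 10)

    def test_incremental_matches_recomputation(self, rng):
        for _ in range(50):
            d = int(rng.integers(1, 6))
            T = int(rng.integers(2 * d + 2, 60))
            y = TimeSeriesMatrix(rng.standard_normal((d, T)) * rng.uniform(0.5, 3))
            ts = range(1, T)
            for pair in iter_scatter_pairs(y, ts):
                ref = compute_scatter_pair(y, pair.t)
                np.testing.assert_allclose(pair.a, ref.a, atol=1e-8)
                np.testing.assert_allclose(pair.b, ref.b, atol=1e-8)


# ---------------------------------------------------------------------------
# greatest root
# ---------------------------------------------------------------------------


def _random_pd(rng, d, scale=1.0):
    m = rng.standard_normal((d, 2 * d))
    return scale * (m @ m.T) / (2 * d) + 0.1 * np.eye(d)


class TestGreatestRoot:
    def test_equal_pair_gives_half(self, rng):
        a = _random_pd(rng, 3)
        phi = greatest_root(ScatterPair(a=a, b=a.copy(), t=10, mean_left=np.zeros(3), mean_right=np.zeros(3)))
        assert phi == pytest.approx(0.5, abs=1e-12)

    def test_diagonal_case(self):
        pair = ScatterPair(
            a=np.diag([3.0, 1.0]), b=np.eye(2), t=5, mean_left=np.zeros(2), mean_right=np.zeros(2)
        )
        assert greatest_root(pair) == pytest.approx(0.75, abs=1e-12)

    def test_determinant_root_scan(self, rng):
        a = _random_pd(rng, 4)
        b = _random_pd(rng, 4)
        pair = ScatterPair(a=a, b=b, t=8, mean_left=np.zeros(4), mean_right=np.zeros(4))
        phi = greatest_root(pair)
        det = lambda x: np.linalg.det(a - x * (a + b))
        assert abs(det(phi)) < 1e-8 * abs(np.linalg.det(a + b))
        # sign-change scan: phi is the LARGEST root — no sign change above it
        grid = np.linspace(phi + 1e-6, 1.0, 200)
        signs = np.sign([det(x) for x in grid])
        assert np.all(signs == signs[0])
        # and the determinant changes sign across phi
        assert det(phi - 1e-6) * det(phi + 1e-6) < 0

    def test_eigenvalue_complementarity(self, rng):
        a = _random_pd(rng, 5)
        b = _random_pd(rng, 5)
        w_a = scipy.linalg.eigh(a, a + b, eigvals_only=True)
        w_b = scipy.linalg.eigh(b, a + b, eigvals_only=True)
        assert w_b[-1] == pytest.approx(1.0 - w_a[0], abs=1e-8)

    def test_scale_invariance_under_linear_map(self, rng):
        a = _random_pd(rng, 4)
        b = _random_pd(rng, 4)
        c = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        mk = lambda m1, m2: ScatterPair(
            a=m1, b=m2, t=9, mean_left=np.zeros(4), mean_right=np.zeros(4)
        )
        phi1 = greatest_root(mk(a, b))
        phi2 = greatest_root(mk(c @ a @ c.T, c @ b @ c.T))
        assert phi1 == pytest.approx(phi2, abs=1e-9)


# ---------------------------------------------------------------------------
# Tracy-Widom centering and standardization
# ---------------------------------------------------------------------------


class TestTWCentering:
    def test_symmetry_when_dim_equals_df(self):
        c = tw_centering(10, 10, 40)
        assert c.gamma_angle == pytest.approx(c.phi_angle, abs=1e-14)
        assert c.mu == pytest.approx(2 * math.log(math.tan(c.phi_angle)), abs=1e-12)

    def test_frozen_high_precision_values(self):
        # 30-digit evaluation of the centering formulas at (d, m, n) = (5, 100, 100)
        c = tw_centering(5, 100, 100)
        assert c.mu == pytest.approx(0.613182601339047066676510426931, abs=1e-13)
        assert c.sigma == pytest.approx(0.114232566391395578705609041429, abs=1e-13)
        assert c.gamma_angle == pytest.approx(0.301898006759809836975789142240, abs=1e-13)
        assert c.phi_angle == pytest.approx(math.pi / 2, abs=1e-13)

    def test_numerator_swap_symmetric_when_df_equal(self):
        c1 = tw_centering(4, 80, 80)
        c2 = tw_centering(4, 80, 80)  # swapping m and n is the identity here
        assert (c1.mu, c1.sigma) == (c2.mu, c2.sigma)
        # and with unequal dfs the swap moves mu
        c3 = tw_centering(4, 60, 100)
        c4 = tw_centering(4, 100, 60)
        assert c3.mu != pytest.approx(c4.mu)

    def test_gamma_never_exceeds_phi(self):
        for m, n in [(30, 170), (100, 100), (170, 30)]:
            c = tw_centering(5, m, n)
            assert c.gamma_angle <= c.phi_angle + 1e-15
            assert c.sigma > 0

    def test_domain_error(self):
        with pytest.raises(ValueError, match="arcsine"):
            tw_centering(5, 2, 2)  # (max(d,m)-0.5)/(m+n-1) > 1

    def test_df_below_dim_strict(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            tw_centering(10, 5, 100, strict=True)


class TestStandardizedLogit:
    def test_logit_half_is_minus_mu_over_sigma(self):
        c = tw_centering(5, 100, 100)
        assert standardized_logit(0.5, c) == pytest.approx(-c.mu / c.sigma, abs=1e-12)

    def test_inverse_logit_of_mu_gives_zero(self):
        c = tw_centering(5, 100, 100)
        phi = 1.0 / (1.0 + math.exp(-c.mu))
        assert standardized_logit(phi, c) == pytest.approx(0.0, abs=1e-12)

    def test_composition(self, rng):
        c = tw_centering(3, 50, 70)
        for phi in rng.uniform(0.01, 0.99, size=10):
            expected = (math.log(phi / (1 - phi)) - c.mu) / c.sigma
            assert standardized_logit(float(phi), c) == pytest.approx(expected, rel=1e-12)

    def test_boundary_error_without_clamp(self):
        c = tw_centering(3, 50, 70)
        with pytest.raises(ValueError, match="boundary"):
            standardized_logit(1.0, c, clamp=False)


# ---------------------------------------------------------------------------
# change process
# ---------------------------------------------------------------------------


def _change_process_from_scratch(y, t_min=None):
    """Non-incremental oracle: recompute every split from scratch with the
    scalar building blocks."""
    d, T = y.d, y.T
    if t_min is None:
        t_min = max(d + 2, 30)
    ts = np.arange(t_min, T - t_min + 1)
    g = np.empty(len(ts))
    for i, t in enumerate(ts):
        pair = compute_scatter_pair(y, int(t))
        w = scipy.linalg.eigh(pair.a, pair.a + pair.b, eigvals_only=True)
        phi_a, phi_b = w[-1], 1.0 - w[0]
        c_a = tw_centering(d, t, T - t)
        c_b = tw_centering(d, T - t, t)
        g[i] = standardized_logit(phi_a, c_a) - standardized_logit(phi_b, c_b)
    return ts, g


class TestChangeProcess:
    def test_duplicated_half_gives_zero_at_midpoint(self, rng):
        half = rng.standard_normal((3, 40))
        y = TimeSeriesMatrix(np.hstack([half, half]))
        proc = change_process(y, t_min=5)
        g_mid = proc.g[list(proc.t_values).index(40)]
        assert g_mid == pytest.approx(0.0, abs=1e-10)

    def test_matches_from_scratch_oracle(self, rng):
        y = TimeSeriesMatrix(rng.standard_normal((5, 120)))
        proc = change_process(y)
        ts, g = _change_process_from_scratch(y)
        np.testing.assert_array_equal(proc.t_values, ts)
        np.testing.assert_allclose(proc.g, g, atol=1e-8)
        assert proc.lambda_T == pytest.approx(np.max(g**2), abs=1e-8)

    def test_null_mean_zero_at_fixed_split(self):
        # under covariance constancy E[G_t] = 0 at any interior split
        t, d, T, reps = 100, 5, 200, 500
        gen = np.random.default_rng(2024)
        vals = np.empty(reps)
        for r in range(reps):
            y = TimeSeriesMatrix(gen.standard_normal((d, T)))
            pair = compute_scatter_pair(y, t)
            w = scipy.linalg.eigh(pair.a, pair.a + pair.b, eigvals_only=True)
            vals[r] = standardized_logit(w[-1], tw_centering(d, t, T - t)) - standardized_logit(
                1.0 - w[0], tw_centering(d, T - t, t)
            )
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean()) < 3 * se

    def test_lambda_nonnegative_and_tau_admissible(self, gaussian_series):
        for seed in range(5):
            y = gaussian_series(d=3, T=90, seed=seed)
            proc = change_process(y)
            assert proc.lambda_T >= 0
            assert proc.tau_hat in proc.t_values
            assert proc.lambda_T == pytest.approx(np.max(proc.g**2))

    def test_tie_resolves_to_smallest_split(self):
        t_values = np.array([30, 31, 32])
        assert _argmax_smallest(t_values, np.array([1.0, 2.0, 2.0])) == 31

    def test_deterministic(self, gaussian_series):
        y = gaussian_series(d=4, T=120, seed=7)
        p1 = change_process(y)
        p2 = change_process(y)
        assert p1.tau_hat == p2.tau_hat
        np.testing.assert_array_equal(p1.g, p2.g)

    def test_t_min_floor_enforced(self, gaussian_series):
        y = gaussian_series(d=5, T=120, seed=1)
        with pytest.raises(ValueError, match="t_min"):
            change_process(y, t_min=3)


class TestDetectAndSegment:
    def test_detect_recovers_strong_variance_change(self, gaussian_series):
        y = gaussian_series(d=3, T=200, seed=5, sigma=np.eye(3), sigma_post=6 * np.eye(3), tau=100)
        res = detect_change_point(y)
        assert abs(res.tau_hat - 100) <= 5
        assert res.theta_hat == pytest.approx(res.tau_hat / 200)

    def test_detect_with_permutation_reports_inference(self, gaussian_series):
        y = gaussian_series(d=3, T=140, seed=3, sigma=np.eye(3), sigma_post=8 * np.eye(3), tau=70)
        res = detect_change_point(y, permutation=PermutationConfig(5, 49, 0.05, seed=11))
        assert res.threshold is not None
        assert 0 < res.p_value <= 1
        assert res.rejected == (res.lambda_T > res.threshold)

    def test_segmentation_null_is_empty(self, gaussian_series):
        y = gaussian_series(d=3, T=150, seed=8)
        pts = binary_segmentation(y, PermutationConfig(5, 99, 0.05, seed=21))
        assert pts == []

    def test_segmentation_recovers_two_changes(self):
        gen = np.random.default_rng(99)
        blocks = [
            1.0 * gen.standard_normal((2, 120)),
            6.0 * gen.standard_normal((2, 120)),
            1.0 * gen.standard_normal((2, 120)),
        ]
        y = TimeSeriesMatrix(np.hstack(blocks))
        pts = binary_segmentation(y, PermutationConfig(5, 99, 0.05, seed=33))
        assert len(pts) == 2
        assert abs(pts[0] - 120) <= 10 and abs(pts[1] - 240) <= 10

    def test_segmentation_short_series_is_empty(self, gaussian_series):
        y = gaussian_series(d=5, T=50, seed=2)  # below twice the default trim
        assert binary_segmentation(y, PermutationConfig(5, 19, 0.05, seed=4)) == []


class TestTimeSeriesMatrix:
    def test_rejects_short_series(self):
        with pytest.raises(ValueError, match="T=10"):
            TimeSeriesMatrix(np.zeros((5, 10)))

    def test_rejects_non_finite(self):
        v = np.zeros((2, 20))
        v[1, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            TimeSeriesMatrix(v)
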