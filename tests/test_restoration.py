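import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import minimize

from ctprestore.restoration import (RestorationParams, adaptive_weight,
                                    gauss_seidel_step, median_map,
                                    median_neighbors, pwls_objective,
                                    pwls_restore, restore)


def smooth_sinogram(rng, shape=(8, 8), scale=1.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return scale * (1.5 + np.sin(rr / 3.0) + 0.5 * np.cos(cc / 2.0))


class TestMedianNeighbors:
    def test_interior_four_neighbors_even_median(self):
        p = np.zeros((3, 3))
        p[0, 1], p[2, 1], p[1, 0], p[1, 2] = 1.0, 2.0, 3.0, 4.0
        assert median_neighbors(p, (1, 1)) == 2.5

    def test_corner_two_neighbors(self):
        p = np.zeros((3, 3))
        p[0, 1], p[1, 0] = 5.0, 9.0
        assert median_neighbors(p, (0, 0)) == 7.0

    def test_constant_sinogram(self):
        p = np.full((4, 5), 3.3)
        med = median_map(p)
        assert np.all(med == 3.3)

    def test_map_agrees_with_pointwise(self, rng):
        p = rng.standard_normal((5, 7))
        med = median_map(p)
        for i in range(5):
            for j in range(7):
                assert med[i, j] == pytest.approx(median_neighbors(p, (i, j)))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            median_neighbors(np.zeros((3, 3)), (3, 0))


class TestObjective:
    def test_zero_at_constant_fit(self):
        y = np.full((4, 4), 2.0)
        var = np.full((4, 4), 0.1)
        assert pwls_objective(y, y, var, beta=5.0) == 0.0

    def test_beta_zero_is_weighted_residual(self, rng):
        y = rng.standard_normal((4, 4))
        p = rng.standard_normal((4, 4))
        var = rng.uniform(0.5, 2.0, (4, 4))
        expected = 0.5 * np.sum((y - p) ** 2 / var)
        assert pwls_objective(p, y, var, 0.0) == pytest.approx(expected)

    def test_2x2_brute_force(self):
        p = np.array([[1.0, 2.0], [3.0, 5.0]])
        y = np.array([[1.5, 1.0], [2.0, 6.0]])
        var = np.array([[0.5, 1.0], [2.0, 0.25]])
        beta = 3.0
        # independent direct summation: each 2x2 element has 2 neighbors
        data = 0.5 * sum((y[i, j] - p[i, j]) ** 2 / var[i, j]
                         for i in range(2) for j in range(2))
        meds = {(0, 0): (2.0 + 3.0) / 2, (0, 1): (1.0 + 5.0) / 2,
                (1, 0): (1.0 + 5.0) / 2, (1, 1): (2.0 + 3.0) / 2}
        rough = 0.5 * sum((p[i, j] - meds[i, j]) ** 2
                          for i in range(2) for j in range(2))
        assert pwls_objective(p, y, var, beta) == pytest.approx(
            data + beta * rough, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pwls_objective(np.ones((2, 2)), np.ones((2, 2)),
                           np.zeros((2, 2)), 1.0)


class TestGaussSeidelStep:
    def test_beta_zero_returns_data(self, rng):
        y = rng.standard_normal((5, 5))
        p = rng.standard_normal((5, 5))
        out = gauss_seidel_step(p, y, np.ones((5, 5)), beta=0.0)
        assert np.array_equal(out, y)

    def test_unit_weight_halfway_update(self):
        # center datum 10, all neighbors at 8 (fixed points), beta*var = 1
        y = np.full((3, 3), 8.0)
        y[1, 1] = 10.0
        p = np.full((3, 3), 8.0)
        out = gauss_seidel_step(p, y, np.ones((3, 3)), beta=1.0)
        assert out[1, 1] == pytest.approx(9.0, abs=1e-14)

    def test_infinite_smoothing_gives_median(self, rng):
        y = rng.uniform(1.0, 2.0, (6, 6))
        p = y.copy()
        out = gauss_seidel_step(p, y, np.ones((6, 6)), beta=1e9)
        # each update must land on the median of its (partly updated) hood
        expected = p.copy()
        for i in range(6):
            for j in range(6):
                expected[i, j] = median_neighbors(expected, (i, j))
        assert out == pytest.approx(expected, rel=1e-6)

    def test_constant_is_fixed_point(self):
        p = np.full((4, 6), 2.5)
        for beta in (0.0, 1.0, 1e6):
            out = gauss_seidel_step(p, p, np.full((4, 6), 0.3), beta)
            assert np.array_equal(out, p)

    def test_sequential_semantics_used(self):
        # raster order: (0,0) updates before (0,1) sees it
        y = np.array([[4.0, 0.0], [0.0, 0.0]])
        p = y.copy()
        var = np.ones((2, 2))
        out = gauss_seidel_step(p, y, var, beta=1.0)
        # (0,0): med(0,0)=0 -> 2; (0,1): neighbors {2(updated),0} med=1 -> 0.5
        assert out[0, 0] == pytest.approx(2.0)
        assert out[0, 1] == pytest.approx(0.5)


class TestPwlsRestore:
    def test_constant_input_converges_immediately(self):
        y = np.full((5, 5), 4.2)
        res = pwls_restore(y, np.full((5, 5), 0.1),
                           RestorationParams(beta=20.0))
        assert res.converged
        assert res.iterations_run == 1
        assert np.array_equal(res.restored, y)
        assert len(res.objective_trace) == res.iterations_run + 1

    def test_beta_zero_identity(self, rng):
        y = rng.uniform(0, 3, (6, 6))
        res = pwls_restore(y, np.ones((6, 6)), RestorationParams(beta=0.0))
        assert res.converged and res.iterations_run == 1
        assert np.array_equal(res.restored, y)

    def test_denoises_toward_clean(self, rng):
        clean = smooth_sinogram(rng)
        var = np.full(clean.shape, 0.02)
        noisy = clean + rng.standard_normal(clean.shape) * np.sqrt(var)
        res = pwls_restore(noisy, var, RestorationParams(beta=50.0))
        rmse_noisy = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_rest = np.sqrt(np.mean((res.restored - clean) ** 2))
        assert rmse_rest < rmse_noisy

    def test_fixed_point_matches_frozen_median_minimizer(self, rng):
        """Converged iterate vs a generic quadratic minimizer of the
        objective with the neighborhood medians frozen at convergence."""
        clean = smooth_sinogram(rng, (6, 6))
        var = np.full(clean.shape, 0.05)
        y = clean + rng.standard_normal(clean.shape) * np.sqrt(var)
        res = pwls_restore(y, var, RestorationParams(beta=30.0, tol=1e-10))
        assert res.converged
        med = median_map(res.restored)

        def phi(pflat):
            p = pflat.reshape(y.shape)
            return (0.5 * np.sum((y - p) ** 2 / var)
                    + 30.0 * 0.5 * np.sum((p - med) ** 2))

        opt = minimize(phi, y.ravel(), method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12})
        assert res.restored.ravel() == pytest.approx(opt.x, rel=1e-4, abs=1e-6)

    def test_update_magnitude_shrinks_after_burn_in(self, rng):
        for _ in range(3):
            clean = smooth_sinogram(rng, (10, 10))
            var = np.full(clean.shape, 0.05)
            y = clean + rng.standard_normal(clean.shape) * np.sqrt(var)
            res = pwls_restore(y, var, RestorationParams(beta=40.0))
            assert res.converged
            deltas = res.delta_trace[3:]
            assert np.all(np.diff(deltas) <= 1e-15)

    def test_sweep_orders_reach_similar_objective(self, rng):
        clean = smooth_sinogram(rng, (12, 12))
        var = np.full(clean.shape, 0.05)
        y = clean + rng.standard_normal(clean.shape) * np.sqrt(var)
        phis = []
        for order in ("raster", "reverse_raster"):
            res = pwls_restore(y, var, RestorationParams(beta=40.0,
                                                         sweep_order=order))
            phis.append(res.objective_trace[-1])
        assert abs(phis[0] - phis[1]) <= 0.005 * abs(phis[0])

    def test_nonfinite_input_rejected(self):
        y = np.ones((3, 3))
        y[1, 1] = np.nan
        with pytest.raises(ValueError):
            pwls_restore(y, np.ones((3, 3)), RestorationParams())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (5, 6),
                      elements=st.floats(-50, 50, allow_nan=False)),
           st.floats(0.0, 1e6))
    def test_range_preservation(self, y, beta):
        res = pwls_restore(y, np.full(y.shape, 0.5),
                           RestorationParams(beta=beta, max_iters=50))
        eps = 1e-9
        assert res.restored.min() >= y.min() - eps
        assert res.restored.max() <= y.max() + eps


class TestAdaptiveWeight:
    def test_infinite_threshold_keeps_raw_data(self, rng):
        y = rng.standard_normal((4, 4))
        x = rng.standard_normal((4, 4))
        out = adaptive_weight(y, x, np.full((4, 4), 0.5), np.inf)
        assert np.array_equal(out, y)

    def test_zero_threshold_takes_restored(self, rng):
        y = rng.standard_normal((4, 4))
        x = rng.standard_normal((4, 4))
        out = adaptive_weight(y, x, np.full((4, 4), 0.5), 0.0)
        assert np.array_equal(out, x)

    def test_mixed_variances_route_elementwise(self):
        y = np.array([[10.0, 20.0]])
        x = np.array([[1.0, 2.0]])
        var = np.array([[0.5, 2.0]])
        out = adaptive_weight(y, x, var, 1.0)
        assert out[0, 0] == 10.0 and out[0, 1] == 2.0


class TestRestoreComposition:
    def test_returns_both_sinograms_and_lambda(self, rng):
        clean = smooth_sinogram(rng)
        var = np.full(clean.shape, 0.02)
        y = clean + rng.standard_normal(clean.shape) * np.sqrt(var)
        res = restore(y, var, RestorationParams(beta=50.0))
        assert res.weighted is not None
        assert res.lambda_used == pytest.approx(np.percentile(var, 75.0))
        # low-variance rays keep the raw datum, high-variance take restored
        keep = var <= res.lambda_used
        assert np.array_equal(res.weighted[keep], y[keep])
        assert np.array_equal(res.weighted[~keep], res.restored[~keep])
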