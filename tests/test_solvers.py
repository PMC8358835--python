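import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scsga.connectivity import correlation_matrix
from scsga.mvar import DesignSystem, build_design, coeffs_to_tensor
from scsga.signal_io import Recording
from scsga.simulate import EASY_REGIME, inject_outliers, sample_sparse_var, simulate_var
from scsga.solvers import (
    SolverConfig,
    fit_l2,
    fit_lapps,
    fit_lasso,
    fit_scsga,
    half_threshold,
    soft_threshold,
    weight_design,
)

from conftest import support_f1


def half_threshold_oracle(z: float, tau: float, lo=-4.0, hi=4.0) -> float:
    """Two-stage brute-force grid minimization of tau*|x|^0.5 + 0.5*(x-z)^2."""
    xs = np.arange(lo, hi, 1e-4)
    obj = tau * np.sqrt(np.abs(xs)) + 0.5 * (xs - z) ** 2
    x0 = xs[np.argmin(obj)]
    xs = np.arange(x0 - 2e-4, x0 + 2e-4, 1e-8)
    obj = tau * np.sqrt(np.abs(xs)) + 0.5 * (xs - z) ** 2
    return float(xs[np.argmin(obj)])


class TestSoftThreshold:
    def test_definition(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([2.0, -0.5]), 1.0), [1.0, 0.0]
        )

    def test_zero_threshold_identity(self, rng):
        z = rng.normal(size=10)
        np.testing.assert_array_equal(soft_threshold(z, 0.0), z)

    def test_zero_vector(self):
        np.testing.assert_array_equal(soft_threshold(np.zeros(5), 3.0), 0.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(2), -0.1)

    @given(
        z=st.floats(-100, 100, allow_nan=False),
        tau=st.floats(0, 50, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_shrinks_toward_zero(self, z, tau):
        out = soft_threshold(np.array([z]), tau)[0]
        assert abs(out) <= abs(z) + 1e-12
        assert out * z >= 0


class TestHalfThreshold:
    def test_zero_fixed_point(self):
        assert half_threshold(np.array([0.0]), 0.7)[0] == 0.0

    def test_no_penalty_identity(self, rng):
        z = rng.normal(size=8)
        np.testing.assert_array_equal(half_threshold(z, 0.0), z)

    def test_matches_grid_oracle_single(self):
        got = half_threshold(np.array([1.0]), 0.2)[0]
        assert abs(got - half_threshold_oracle(1.0, 0.2)) < 1e-6

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            half_threshold(np.ones(2), -1.0)

    def test_small_inputs_zeroed(self):
        tau = 0.5
        cutoff = (54.0 ** (1 / 3) / 4) * tau ** (2 / 3)
        z = np.array([cutoff * 0.99, -cutoff * 0.5])
        np.testing.assert_array_equal(half_threshold(z, tau), 0.0)

    def test_odd_symmetry(self, rng):
        z = rng.normal(size=10) * 3
        np.testing.assert_allclose(
            half_threshold(-z, 0.3), -half_threshold(z, 0.3), atol=1e-12
        )


class TestFitL2:
    def test_noiseless_ar1_exact(self):
        w = 0.5 ** np.arange(20)
        ds = build_design(
            Recording(data=np.vstack([w, w]), srate=1.0), s=1, k=0
        )
        # keep only the target channel's own block to isolate the AR(1)
        ds1 = DesignSystem(A=ds.A[:, :1], y=ds.y, s=1, k=0, m=1, n=20)
        fit = fit_l2(ds1)
        np.testing.assert_allclose(fit.coeffs, [0.5], atol=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_duplicated_columns_min_norm(self, rng):
        x = rng.normal(size=60)
        rec = Recording(data=np.vstack([x, x]), srate=1.0)
        ds = build_design(rec, s=2, k=0)
        fit = fit_l2(ds)  # must not raise despite exact collinearity
        assert np.all(np.isfinite(fit.coeffs))
        assert fit.rank < ds.A.shape[1]

    def test_matches_normal_equations_oracle(self, rng):
        # independently coded closed form on a well-conditioned system
        rec = Recording(data=rng.normal(size=(5, 200)), srate=1.0)
        ds = build_design(rec, s=3, k=2)
        oracle = np.linalg.solve(ds.A.T @ ds.A, ds.A.T @ ds.y)
        fit = fit_l2(ds)
        np.testing.assert_allclose(fit.coeffs, oracle, rtol=1e-8, atol=1e-10)


class TestFitLasso:
    def test_zero_penalty_matches_l2(self, rng):
        rec = Recording(data=rng.normal(size=(3, 150)), srate=1.0)
        ds = build_design(rec, s=2, k=0)
        lasso = fit_lasso(ds, SolverConfig(lam=0.0, max_iter=2000))
        l2 = fit_l2(ds)
        np.testing.assert_allclose(lasso.coeffs, l2.coeffs, atol=1e-6)

    def test_one_dim_closed_form(self):
        # A=[[1]], y=[2], lam=2 -> x = soft(A'y, lam/2)/(A'A) = 1
        ds = DesignSystem(
            A=np.array([[1.0]]), y=np.array([2.0]), s=1, k=0, m=1, n=2
        )
        fit = fit_lasso(ds, SolverConfig(lam=2.0))
        np.testing.assert_allclose(fit.coeffs, [1.0], atol=1e-10)

    def test_null_solution_bound(self, rng):
        rec = Recording(data=rng.normal(size=(3, 100)), srate=1.0)
        ds = build_design(rec, s=2, k=1)
        lam = 2.0 * np.abs(ds.A.T @ ds.y).max()
        fit = fit_lasso(ds, SolverConfig(lam=lam))
        np.testing.assert_array_equal(fit.coeffs, 0.0)

    def test_objective_non_increasing(self, rng):
        rec = Recording(data=rng.normal(size=(4, 120)), srate=1.0)
        ds = build_design(rec, s=2, k=0)
        fit = fit_lasso(ds, SolverConfig(lam=1.0))
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_sparsity_monotone_in_lambda(self, easy_rec):
        ds = build_design(easy_rec, s=2, k=0)
        grid = np.logspace(-2, 2, 10)
        nnz = [
            np.count_nonzero(fit_lasso(ds, SolverConfig(lam=float(l))).coeffs)
            for l in grid
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestFitLapps:
    def test_feasibility_sparse_span(self, rng):
        # y generated exactly by a sparse x; tiny penalty must reproduce it
        A = rng.normal(size=(80, 20))
        x_true = np.zeros(20)
        x_true[[2, 7, 13]] = [1.5, -2.0, 0.8]
        y = A @ x_true
        ds = DesignSystem(A=A, y=y, s=1, k=0, m=20, n=81)
        fit = fit_lapps(ds, SolverConfig(lam=1e-8, max_iter=2000))
        rel = np.abs(A @ np.where(fit.coeffs == 0, 0, fit.coeffs) - y).sum() / np.abs(y).sum()
        assert rel < 1e-3

    def test_identity_design_separable_oracle(self):
        y = np.array([2.0, -1.5, 0.05, 0.8, -3.0, 0.3])
        ds = DesignSystem(A=np.eye(6), y=y, s=1, k=0, m=6, n=7)
        cfg = SolverConfig(lam=0.3, eta=1.0, rho=5.0, max_iter=3000,
                           tol_abs=1e-10, tol_rel=1e-8)
        fit = fit_lapps(ds, cfg)

        def oracle_1d(v):
            xs = np.arange(-4, 4, 1e-4)
            obj = np.abs(xs - v) / cfg.eta + cfg.lam * np.sqrt(np.abs(xs))
            x0 = xs[np.argmin(obj)]
            xs = np.arange(x0 - 2e-4, x0 + 2e-4, 1e-7)
            obj = np.abs(xs - v) / cfg.eta + cfg.lam * np.sqrt(np.abs(xs))
            return xs[np.argmin(obj)]

        oracle = np.array([oracle_1d(v) for v in y])
        np.testing.assert_allclose(fit.coeffs, oracle, atol=1e-4)

    def test_zero_y_zero_solution(self, rng):
        A = rng.normal(size=(30, 10))
        ds = DesignSystem(A=A, y=np.zeros(30), s=1, k=0, m=10, n=31)
        fit = fit_lapps(ds, SolverConfig(lam=0.5))
        np.testing.assert_array_equal(fit.coeffs, 0.0)

    def test_admm_state_recorded(self, easy_rec):
        ds = build_design(easy_rec, s=2, k=0)
        fit = fit_lapps(ds, SolverConfig(lam=0.1, max_iter=50))
        state = fit.admm_state
        assert len(state.primal_res) == fit.n_iter
        assert all(v >= 0 for v in state.primal_res)
        assert all(v >= 0 for v in state.dual_res)


class TestWeightDesign:
    def test_all_ones_unchanged(self, easy_rec):
        ds = build_design(easy_rec, s=2, k=0)
        out = weight_design(ds, np.ones((8, 8)))
        np.testing.assert_array_equal(out.A, ds.A)
        np.testing.assert_array_equal(out.weights, 1.0)

    def test_halved_block(self, small_rec):
        ds = build_design(small_rec, s=2, k=0)
        E = np.eye(4)
        E[1, 0] = E[0, 1] = 0.5
        out = weight_design(ds, E)
        np.testing.assert_allclose(out.A[:, 2:4], 0.5 * ds.A[:, 2:4])
        np.testing.assert_array_equal(out.A[:, 0:2], ds.A[:, 0:2])

    def test_zero_weight_annihilates_block(self, small_rec):
        ds = build_design(small_rec, s=2, k=0)
        E = np.ones((4, 4))
        E[2, 0] = E[0, 2] = 0.0
        out = weight_design(ds, E)
        np.testing.assert_array_equal(out.A[:, 4:6], 0.0)
        fit = fit_lapps(out, SolverConfig(lam=0.1, max_iter=100))
        np.testing.assert_array_equal(fit.coeffs[4:6], 0.0)

    def test_dimension_mismatch(self, small_rec):
        ds = build_design(small_rec, s=2, k=0)
        with pytest.raises(ValueError, match="shape"):
            weight_design(ds, np.ones((3, 3)))


class TestFitScsga:
    def test_all_ones_reduces_to_lapps(self, easy_rec):
        ds = build_design(easy_rec, s=2, k=0)
        cfg = SolverConfig(lam=0.1)
        a = fit_scsga(ds, np.ones((8, 8)), cfg)
        b = fit_lapps(ds, cfg)
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-6)

    def test_uniform_offdiagonal_same_support(self, easy_rec):
        ds = build_design(easy_rec, s=2, k=0)
        cfg = SolverConfig(lam=0.05, max_iter=1000)
        base = fit_lapps(ds, cfg)
        c = 0.5  # unit diagonal, uniform |off-diagonal| = c
        E = np.where(np.eye(8, dtype=bool), 1.0, c)
        # scaling every non-self block by the same c preserves which
        # predictors can enter at a matched effective penalty level
        scaled = fit_scsga(ds, E, cfg)
        # compare supports restricted to the target's own block, which is
        # unscaled in both problems
        s = ds.s
        k = ds.k
        own = slice(k * s, (k + 1) * s)
        assert np.array_equal(base.coeffs[own] != 0, scaled.coeffs[own] != 0)

    def test_uncorrelated_noisy_channel_suppressed(self, rng):
        # channel 2 is huge-amplitude noise, uncorrelated with target 0;
        # correlation weighting must zero its edge onto the target
        n = 300
        noise = rng.normal(size=(3, n))
        data = np.zeros((3, n))
        for t in range(1, n):
            data[0, t] = 0.6 * data[0, t - 1] + noise[0, t]
            data[1, t] = 0.5 * data[1, t - 1] + 0.3 * data[0, t - 1] + noise[1, t]
            data[2, t] = 50.0 * noise[2, t]
        data -= data.mean(axis=1, keepdims=True)
        rec = Recording(data=data, srate=100.0)
        E = correlation_matrix(rec).M
        assert abs(E[2, 0]) < 0.15
        ds = build_design(rec, s=1, k=0)
        cfg = SolverConfig(lam=5.0)
        sc = fit_scsga(ds, E, cfg)
        lp = fit_lapps(ds, cfg)
        assert sc.coeffs[2] == 0.0
        assert lp.coeffs[2] != 0.0
        # the genuine self-lag survives the weighting
        assert abs(sc.coeffs[0] - 0.6) < 0.15


def test_robustness_lapps_beats_l2_under_outliers(easy_truth):
    # contaminated regime: squared loss inflates spurious coefficients
    spec = EASY_REGIME
    rec = simulate_var(easy_truth, spec)
    rec, _ = inject_outliers(rec, 0.05, 10.0, seed=999)
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    rec = Recording(data=data, srate=rec.srate)
    tensors = {}
    for name, fit_fn in [
        ("l2", lambda ds: fit_l2(ds)),
        ("lapps", lambda ds: fit_lapps(ds, SolverConfig(lam=0.1))),
    ]:
        fits = [fit_fn(build_design(rec, spec.s, k)) for k in range(spec.m)]
        tensors[name] = coeffs_to_tensor(fits, spec.m, spec.s)
    rmse = {
        k: float(np.sqrt(np.mean((t - easy_truth.tensor) ** 2)))
        for k, t in tensors.items()
    }
    assert rmse["lapps"] < rmse["l2"]


def test_scsga_support_recovery_clean(easy_truth, easy_rec):
    from scsga.connectivity import aggregate_network

    E = correlation_matrix(easy_rec).M
    cfg = SolverConfig(lam=0.1)
    fits = [
        fit_scsga(build_design(easy_rec, 2, k), E, cfg) for k in range(8)
    ]
    G = aggregate_network(coeffs_to_tensor(fits, 8, 2)).G
    assert support_f1(G, easy_truth.support) >= 0.9


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(lam=-1.0)
    with pytest.raises(ValueError):
        SolverConfig(eta=0.0)
    with pytest.raises(ValueError):
        SolverConfig(rho=-2.0)
    with pytest.raises(ValueError):
        SolverConfig(weight_mode="bogus")
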