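"""Reduced exponential-family model: fit, predictions, gauge, recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dfftcourt import (CourtGrid, DFFTModel, DPModel, conditional_defense,
                       default_truth, fit_dfft, fit_dp, gauge_transform,
                       kl_objective, loglik, predict_bin, sample_states)
from dfftcourt.dfft import _standard_gauge, conditional_defense_means


def two_bin_grid():
    return CourtGrid(0, 10, 0, 5, 5)


def dirichlet_empirical(grid, L, seed):
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.ones(L * L), size=grid.n_bins).reshape(-1, L, L)
    return DPModel(grid, L, 0.0, P)


def brute_force_fit(P, seeds=(0, 1)):
    """Independent oracle: direct numerical minimization of the summed
    per-bin KL objective over all (f, v) parameters."""
    B, L, _ = P.shape
    n = np.arange(L, dtype=float)

    def kl(theta):
        f = theta[:L * L].reshape(L, L)
        vo = theta[L * L:L * L + B]
        vd = theta[L * L + B:]
        E = (vo[:, None, None] * n[None, :, None]
             + vd[:, None, None] * n[None, None, :] + f[None])
        E = E - E.min(axis=(1, 2), keepdims=True)
        w = np.exp(-E)
        Q = w / w.sum(axis=(1, 2), keepdims=True)
        return float((P * np.log(P / Q)).sum())

    best = None
    for s in seeds:
        x0 = np.random.default_rng(s).normal(0, 0.3, L * L + 2 * B)
        res = minimize(kl, x0, method="BFGS",
                       options=dict(maxiter=20000, gtol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    f = best.x[:L * L].reshape(L, L)
    return best.fun, _standard_gauge(f, best.x[L * L:L * L + B],
                                     best.x[L * L + B:])


class TestFitDFFT:
    def test_homogeneous_bins_identity(self, grid):
        """All bins share one pmf: v = 0 and the shared pmf is reproduced."""
        rng = np.random.default_rng(0)
        pmf = rng.dirichlet(np.ones(400)).reshape(20, 20)
        emp = DPModel(grid, 20, 0.0, np.broadcast_to(pmf, (100, 20, 20)).copy())
        model, rep = fit_dfft(emp)
        assert rep.converged
        assert np.allclose(model.v_o, 0, atol=1e-6)
        assert np.allclose(model.v_d, 0, atol=1e-6)
        assert np.allclose(model.prob_table()[0], pmf, atol=1e-8)
        assert rep.objective < 1e-10

    def test_single_bin_is_saturated(self):
        grid = CourtGrid(0, 5, 0, 5, 5)
        emp = dirichlet_empirical(grid, 4, seed=3)
        model, rep = fit_dfft(emp)
        assert rep.objective < 1e-9

    def test_matches_brute_force_on_toy(self):
        """2-bin, 3-level problem against direct numerical minimization."""
        emp = dirichlet_empirical(two_bin_grid(), 3, seed=7)
        model, rep = fit_dfft(emp)
        obj_o, (f_o, vo_o, vd_o) = brute_force_fit(emp.table)
        f_p, vo_p, vd_p = _standard_gauge(model.f, model.v_o, model.v_d)
        assert rep.objective == pytest.approx(obj_o, abs=1e-6)
        assert np.abs(f_p - f_o).max() < 1e-3
        assert np.abs(vo_p - vo_o).max() < 1e-3
        assert np.abs(vd_p - vd_o).max() < 1e-3

    def test_moment_and_state_matching(self, grid):
        truth = default_truth()
        emp = fit_dp(sample_states(truth, 2000, seed=5), alpha=0.1)
        model, rep = fit_dfft(emp)
        assert rep.converged
        P, Q = emp.table, model.prob_table()
        n = np.arange(20.)
        assert np.abs(np.einsum("blm,l->b", Q - P, n)).max() < 1e-6
        assert np.abs(np.einsum("blm,m->b", Q - P, n)).max() < 1e-6
        obs = P.sum(axis=0) > 0
        assert np.abs((Q - P).sum(axis=0))[obs].max() < 1e-6

    def test_objective_non_increasing(self, grid):
        emp = fit_dp(sample_states(default_truth(), 500, seed=6), alpha=0.1)
        _, rep = fit_dfft(emp)
        h = np.array(rep.objective_history)
        assert np.all(np.diff(h) <= 1e-10)
        assert h[-1] >= 0

    def test_rejects_unnormalized_input(self, grid):
        emp = fit_dp(sample_states(default_truth(), 50, seed=1), alpha=0.1)
        emp.table = emp.table * 1.5
        with pytest.raises(ValueError, match="normalized"):
            fit_dfft(emp)

    def test_gauge_conditions_after_fit(self, grid):
        emp = fit_dp(sample_states(default_truth(), 300, seed=2), alpha=0.1)
        model, _ = fit_dfft(emp)
        assert abs(model.v_o.mean()) < 1e-12
        assert abs(model.v_d.mean()) < 1e-12
        assert model.f[0, 0] == 0.0
        assert model.n_parameters == 600


class TestPredictions:
    def test_flat_parameters_give_uniform_pmf(self):
        grid = two_bin_grid()
        m = DFFTModel(grid, 20, np.zeros((20, 20)), np.zeros(2), np.zeros(2))
        assert np.allclose(predict_bin(m, 0), 1 / 400)

    def test_increasing_vd_decreases_mean_defense(self):
        grid = two_bin_grid()
        rng = np.random.default_rng(4)
        f = rng.normal(0, 0.3, (20, 20))
        n = np.arange(20.)
        means = []
        for vd in (-0.2, 0.0, 0.4, 1.0):
            m = DFFTModel(grid, 20, f, np.zeros(2), np.array([vd, 0.0]))
            pmf = predict_bin(m, 0)
            means.append(pmf.sum(axis=0) @ n)
        assert np.all(np.diff(means) < 0)

    def test_predict_matches_direct_summation(self):
        grid = two_bin_grid()
        rng = np.random.default_rng(9)
        m = DFFTModel(grid, 5, rng.normal(0, 1, (5, 5)),
                      rng.normal(0, 0.3, 2), rng.normal(0, 0.3, 2))
        n = np.arange(5.)
        for b in (0, 1):
            E = (n[:, None] * m.v_o[b] + n[None, :] * m.v_d[b] + m.f)
            w = np.exp(-E)
            assert np.allclose(predict_bin(m, b), w / w.sum(), atol=1e-12)

    def test_conditional_separable_f_independent_of_no(self):
        grid = two_bin_grid()
        n = np.arange(20.)
        f = 0.1 * n[:, None] ** 2 + 0.2 * n[None, :]  # no coupling
        m = DFFTModel(grid, 20, f, np.zeros(2), np.array([0.1, -0.1]))
        pmf0, mean0 = conditional_defense(m, 0, 0)
        pmf9, mean9 = conditional_defense(m, 0, 9)
        assert np.allclose(pmf0, pmf9, atol=1e-12)
        assert mean0 == pytest.approx(mean9)

    def test_conditional_coupling_raises_mean_with_no(self):
        grid = two_bin_grid()
        n = np.arange(20.)
        f = 0.1 * n[:, None] ** 2 + 0.1 * n[None, :] ** 2 - 0.05 * np.outer(n, n)
        m = DFFTModel(grid, 20, f, np.zeros(2), np.zeros(2))
        means = [conditional_defense(m, 0, k)[1] for k in range(10)]
        assert np.all(np.diff(means) > 0)

    def test_conditional_matches_row_normalization(self):
        grid = two_bin_grid()
        rng = np.random.default_rng(11)
        m = DFFTModel(grid, 8, rng.normal(0, 0.5, (8, 8)),
                      rng.normal(0, 0.2, 2), rng.normal(0, 0.2, 2))
        pmf_full = predict_bin(m, 1)
        for no in (0, 3, 7):
            row = pmf_full[no] / pmf_full[no].sum()
            pmf, mean = conditional_defense(m, 1, no)
            assert np.allclose(pmf, row, atol=1e-12)
            assert mean == pytest.approx(row @ np.arange(8.))
        # vectorized table agrees with the scalar routine
        tbl = conditional_defense_means(m)
        assert tbl[1, 3] == pytest.approx(conditional_defense(m, 1, 3)[1])


class TestKLObjective:
    def test_identical_distributions_zero(self, grid):
        truth = default_truth()
        m = truth.model()
        emp = DPModel(grid, 20, 0.0, m.prob_table().copy())
        assert kl_objective(emp, m) == pytest.approx(0.0, abs=1e-10)

    def test_nonnegative_and_matches_hand_computation(self):
        grid = CourtGrid(0, 5, 0, 5, 5)
        P = np.array([[[0.5, 0.25], [0.125, 0.125]]])
        emp = DPModel(grid, 2, 0.0, P)
        m = DFFTModel(grid, 2, np.zeros((2, 2)), np.zeros(1), np.zeros(1))
        expected = float((P * np.log(P / 0.25)).sum())
        assert kl_objective(emp, m) == pytest.approx(expected)
        assert expected > 0


class TestGaugeInvariance:
    def test_transform_preserves_probabilities(self, grid, rng):
        emp = fit_dp(sample_states(default_truth(), 300, seed=8), alpha=0.1)
        model, _ = fit_dfft(emp)
        g = gauge_transform(model, a=0.37, c=-1.21, const=4.2)
        assert np.abs(g.prob_table() - model.prob_table()).max() < 1e-10
        from dfftcourt import DensityState
        s = DensityState(grid, rng.integers(0, 20, 100), rng.integers(0, 20, 100))
        assert abs(loglik(g, s) - loglik(model, s)) < 1e-10


class TestRecovery:
    def test_parameter_recovery_from_truth_samples(self):
        """sample_states -> fit closes the loop on (f, v) and held-out fit."""
        truth = default_truth()
        emp = fit_dp(sample_states(truth, 20000, seed=13), alpha=0.0)
        model, rep = fit_dfft(emp)
        assert rep.converged
        tm = truth.model()
        f_t, vo_t, vd_t = _standard_gauge(tm.f, tm.v_o, tm.v_d)
        f_p, vo_p, vd_p = _standard_gauge(model.f, model.v_o, model.v_d)
        obs = emp.table.sum(axis=0) > 0
        assert np.corrcoef(f_t[obs], f_p[obs])[0, 1] > 0.99
        assert np.corrcoef(np.r_[vo_t, vd_t], np.r_[vo_p, vd_p])[0, 1] > 0.99

    def test_dfft_beats_dp_on_heldout_at_small_n(self):
        """In-family generator: the 600-parameter model generalizes better
        than the 40,000-parameter table from few samples."""
        truth = default_truth()
        train = sample_states(truth, 300, seed=14)
        test = sample_states(truth, 500, seed=15)
        dp = fit_dp(train, alpha=0.1)
        dfft, _ = fit_dfft(dp)
        ll_dp = np.mean([loglik(dp, s) for s in test])
        ll_dfft = np.mean([loglik(dfft, s) for s in test])
        assert ll_dfft >= ll_dp


def test_save_load_roundtrip(tmp_path):
    grid = two_bin_grid()
    rng = np.random.default_rng(21)
    m = DFFTModel(grid, 20, rng.normal(0, 1, (20, 20)), rng.normal(0, 1, 2),
                  rng.normal(0, 1, 2), {"outcome": 2})
    path = tmp_path / "m.npz"
    m.save(path)
    m2 = DFFTModel.load(path)
    assert np.array_equal(m.f, m2.f)
    assert np.array_equal(m.v_o, m2.v_o)
    assert m2.meta["outcome"] == 2
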