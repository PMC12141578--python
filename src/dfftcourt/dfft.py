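"""Reduced exponential-family (DFFT) model of the per-bin joint densities.

The direct per-bin tables are compressed to

    P~_b(n_o, n_d) = Z_b^{-1} exp(-n_o v_o,b - n_d v_d,b - f(n_o, n_d)),

a shared interaction function ``f`` (L x L values, capturing the
bin-universal coupling between the two groups' densities) plus one potential
per bin and group (lower v marks locations the group prefers). At the
defaults this is 2*100 + 400 = 600 parameters against the direct table's
40,000.

Fitting minimizes the summed per-bin KL divergence KL(P_b || P~_b), which is
convex up to flat gauge directions, by alternating:

(a) per-bin 2-D Newton tilts so the model means E[n_o], E[n_d] match the
    empirical bin means (moments are strictly monotone in v);
(b) damped iterative proportional scaling of ``f`` toward the stationarity
    condition sum_b P~_b(s) = sum_b P_b(s) for every state s;
(c) re-gauging so mean_b v_o = mean_b v_d = 0 and f(0, 0) = 0.

States never observed in any bin leave f unconstrained; their f is pinned at
a large finite cap so probabilities stay positive and loglikelihoods finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .density import CourtGrid
from .dp import DPModel

__all__ = ["DFFTModel", "FitReport", "FitOptions", "fit_dfft", "predict_bin",
           "conditional_defense", "conditional_defense_means",
           "kl_objective", "gauge_transform"]

#: Cap on f for states with zero empirical mass everywhere.
F_MAX = 50.0


@dataclass
class DFFTModel:
    """Shared interaction ``f`` (L, L) and per-bin potentials v_o, v_d (B,)."""

    grid: CourtGrid
    n_levels: int
    f: np.ndarray
    v_o: np.ndarray
    v_d: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        B, L = self.grid.n_bins, self.n_levels
        self.f = np.asarray(self.f, dtype=float)
        self.v_o = np.asarray(self.v_o, dtype=float)
        self.v_d = np.asarray(self.v_d, dtype=float)
        if self.f.shape != (L, L):
            raise ValueError(f"f must have shape {(L, L)}")
        if self.v_o.shape != (B,) or self.v_d.shape != (B,):
            raise ValueError(f"potentials must have shape {(B,)}")
        self._log_table = None

    @property
    def n_parameters(self) -> int:
        return 2 * self.grid.n_bins + self.n_levels ** 2

    def energies(self) -> np.ndarray:
        """(B, L, L) unnormalized energies n_o v_o,b + n_d v_d,b + f."""
        L = self.n_levels
        n = np.arange(L, dtype=float)
        return (self.v_o[:, None, None] * n[None, :, None]
                + self.v_d[:, None, None] * n[None, None, :]
                + self.f[None, :, :])

    def log_prob_table(self) -> np.ndarray:
        """(B, L, L) log P~_b, normalized stably via max-subtraction."""
        if self._log_table is None:
            E = self.energies()
            logZ = logsumexp(-E, axis=(1, 2), keepdims=True)
            self._log_table = -E - logZ
        return self._log_table

    def prob_table(self) -> np.ndarray:
        return np.exp(self.log_prob_table())

    def _invalidate(self):
        self._log_table = None

    def save(self, path) -> None:
        header = {"model_type": "dfft", "n_levels": self.n_levels,
                  "grid": [self.grid.x_min, self.grid.x_max, self.grid.y_min,
                           self.grid.y_max, self.grid.bin_size],
                  "meta": self.meta}
        np.savez(path, header=json.dumps(header), f=self.f,
                 v_o=self.v_o, v_d=self.v_d)

    @classmethod
    def load(cls, path) -> "DFFTModel":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header["model_type"] != "dfft":
                raise ValueError("not a DFFT model file")
            grid = CourtGrid(*header["grid"])
            return cls(grid, header["n_levels"], z["f"], z["v_o"], z["v_d"],
                       header.get("meta", {}))


@dataclass
class FitReport:
    objective: float
    iterations: int
    max_param_change: float
    converged: bool
    objective_history: list = field(default_factory=list)


@dataclass(frozen=True)
class FitOptions:
    tol_objective: float = 1e-8
    tol_param: float = 1e-6
    max_iter: int = 5000
    damping: float = 0.5
    f_max: float = F_MAX
    v_max: float = 30.0   # cap for degenerate bins whose target mean is 0 or L-1
    newton_iter: int = 50
    newton_tol: float = 1e-10


def gauge_transform(model: DFFTModel, a: float, c: float,
                    const: float = 0.0) -> DFFTModel:
    """Apply the flat-direction transform f += a n_o + c n_d + const,
    v_o -= a, v_d -= c. Leaves every bin pmf unchanged."""
    L = model.n_levels
    n = np.arange(L, dtype=float)
    f = model.f + a * n[:, None] + c * n[None, :] + const
    return DFFTModel(model.grid, L, f, model.v_o - a, model.v_d - c,
                     dict(model.meta))


def _standard_gauge(f, v_o, v_d):
    a, c = v_o.mean(), v_d.mean()
    L = f.shape[0]
    n = np.arange(L, dtype=float)
    f = f + a * n[:, None] + c * n[None, :]
    f = f - f[0, 0]
    return f, v_o - a, v_d - c


def kl_objective(empirical: DPModel, model: DFFTModel) -> float:
    """sum_b sum_s P_b(s) ln(P_b(s) / P~_b(s)) with 0 ln 0 = 0."""
    P = empirical.table
    logQ = model.log_prob_table()
    mask = P > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, P * (np.log(np.where(mask, P, 1.0)) - logQ), 0.0)
    return float(terms.sum())


def predict_bin(model: DFFTModel, b: int) -> np.ndarray:
    """Normalized (L, L) pmf over (n_o, n_d) for bin ``b``."""
    if not 0 <= b < model.grid.n_bins:
        raise IndexError(f"bin {b} out of range")
    return np.exp(model.log_prob_table()[b])


def conditional_defense(model: DFFTModel, b: int, n_o: int):
    """Conditional pmf P~_b(n_d | n_o) and its mean.

    P~_b(n_d | n_o) is proportional to exp(-n_d v_d,b - f(n_o, n_d)).
    """
    L = model.n_levels
    if not 0 <= n_o < L:
        raise IndexError(f"offensive level {n_o} out of range")
    n = np.arange(L, dtype=float)
    logw = -(n * model.v_d[b] + model.f[n_o, :])
    logw -= logw.max()
    pmf = np.exp(logw)
    pmf /= pmf.sum()
    return pmf, float(pmf @ n)


def conditional_defense_means(model: DFFTModel) -> np.ndarray:
    """(n_bins, L) table of E[n_d | n_o] for every bin and offensive level."""
    L = model.n_levels
    n = np.arange(L, dtype=float)
    # weights over n_d for each (bin, n_o)
    logw = -(model.v_d[:, None, None] * n[None, None, :]
             + model.f[None, :, :])
    logw -= logw.max(axis=2, keepdims=True)
    w = np.exp(logw)
    return (w @ n) / w.sum(axis=2)


def _moments(prob):
    """Per-bin means/covariances of (n_o, n_d) under (B, L, L) pmfs."""
    L = prob.shape[1]
    n = np.arange(L, dtype=float)
    po = prob.sum(axis=2)  # (B, L) marginal of n_o
    pd = prob.sum(axis=1)
    m_o = po @ n
    m_d = pd @ n
    var_o = po @ n ** 2 - m_o ** 2
    var_d = pd @ n ** 2 - m_d ** 2
    e_od = np.einsum("blm,l,m->b", prob, n, n)
    cov = e_od - m_o * m_d
    return m_o, m_d, var_o, var_d, cov


def _prob_from(f, v_o, v_d):
    L = f.shape[0]
    n = np.arange(L, dtype=float)
    E = (v_o[:, None, None] * n[None, :, None]
         + v_d[:, None, None] * n[None, None, :] + f[None, :, :])
    E -= E.min(axis=(1, 2), keepdims=True)
    w = np.exp(-E)
    return w / w.sum(axis=(1, 2), keepdims=True)


def _dual(f, v_o, v_d, m_o, m_d):
    """Per-bin convex dual of moment matching: ln Z_b(v) + v . m_emp."""
    L = f.shape[0]
    n = np.arange(L, dtype=float)
    E = (v_o[:, None, None] * n[None, :, None]
         + v_d[:, None, None] * n[None, None, :] + f[None, :, :])
    return logsumexp(-E, axis=(1, 2)) + v_o * m_o + v_d * m_d


def _match_moments(f, v_o, v_d, m_o_emp, m_d_emp, n_iter, tol, v_max=30.0):
    """Per-bin damped Newton on the convex dual so model means match the
    empirical means; backtracking keeps every bin's dual decreasing.

    Potentials are capped at ``|v| <= v_max``: a bin whose empirical mean
    sits exactly at a boundary level (0 or L-1) has its matching potential
    at infinity, and the cap makes such bins effectively degenerate without
    stalling the outer loop.
    """
    for _ in range(n_iter):
        prob = _prob_from(f, v_o, v_d)
        m_o, m_d, var_o, var_d, cov = _moments(prob)
        r_o = m_o - m_o_emp
        r_d = m_d - m_d_emp
        if max(np.abs(r_o).max(), np.abs(r_d).max()) < tol:
            break
        det = var_o * var_d - cov ** 2
        det = np.where(det < 1e-12, 1e-12, det)
        dv_o = (var_d * r_o - cov * r_d) / det
        dv_d = (-cov * r_o + var_o * r_d) / det
        phi0 = _dual(f, v_o, v_d, m_o_emp, m_d_emp)
        # directional derivative is -(r . dv) <= 0 by convexity
        slope = -(r_o * dv_o + r_d * dv_d)
        t = np.ones_like(v_o)
        for _bt in range(40):
            phi1 = _dual(f, v_o + t * dv_o, v_d + t * dv_d, m_o_emp, m_d_emp)
            bad = phi1 > phi0 + 1e-4 * t * slope + 1e-12
            if not bad.any():
                break
            t[bad] *= 0.5
        v_o_new = np.clip(v_o + t * dv_o, -v_max, v_max)
        v_d_new = np.clip(v_d + t * dv_d, -v_max, v_max)
        step = max(np.abs(v_o_new - v_o).max(), np.abs(v_d_new - v_d).max())
        v_o, v_d = v_o_new, v_d_new
        if step < 1e-12:  # every unpinned bin has converged
            break
    return v_o, v_d


def fit_dfft(empirical: DPModel, opts: FitOptions | None = None,
             meta: dict | None = None) -> tuple[DFFTModel, FitReport]:
    """Fit the reduced model by alternating moment matching and damped
    iterative scaling on the summed per-bin KL objective.

    Raises if the empirical tables are not normalized; non-convergence at
    ``max_iter`` is reported via ``FitReport.converged = False``, never
    silently.
    """
    if opts is None:
        opts = FitOptions()
    P = empirical.table
    B, L, _ = P.shape
    if not np.allclose(P.sum(axis=(1, 2)), 1.0, atol=1e-9):
        raise ValueError("empirical tables must be normalized per bin")

    n = np.arange(L, dtype=float)
    m_o_emp = np.einsum("blm,l->b", P, n)
    m_d_emp = np.einsum("blm,m->b", P, n)
    Q_emp = P.sum(axis=0)              # state mass summed over bins
    observed = Q_emp > 0
    logQ_emp = np.where(observed, np.log(np.where(observed, Q_emp, 1.0)), 0.0)

    # init: exact for homogeneous bins
    Pbar = P.mean(axis=0)
    with np.errstate(divide="ignore"):
        f = np.where(Pbar > 0, -np.log(np.where(Pbar > 0, Pbar, 1.0)), opts.f_max)
    f = np.minimum(f, opts.f_max)
    f -= f[0, 0]
    v_o = np.zeros(B)
    v_d = np.zeros(B)

    history = []
    prev_obj = np.inf
    max_delta = np.inf
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        f_old, vo_old, vd_old = f.copy(), v_o.copy(), v_d.copy()

        # (a) per-bin Newton on (v_o, v_d): match empirical means
        v_o, v_d = _match_moments(f, v_o, v_d, m_o_emp, m_d_emp,
                                  opts.newton_iter, opts.newton_tol,
                                  opts.v_max)

        # (b) damped iterative scaling of f toward state-mass matching
        prob = _prob_from(f, v_o, v_d)
        Q_mod = prob.sum(axis=0)
        with np.errstate(divide="ignore"):
            logQ_mod = np.log(np.where(Q_mod > 0, Q_mod, 1e-300))
        f = np.where(observed,
                     f + opts.damping * (logQ_mod - logQ_emp),
                     opts.f_max)

        # (c) re-gauge
        f, v_o, v_d = _standard_gauge(f, v_o, v_d)
        f = np.minimum(f, opts.f_max)

        # convergence bookkeeping on the gauge-fixed parameters
        fg_old, vo_g, vd_g = _standard_gauge(f_old, vo_old, vd_old)
        max_delta = max(np.abs(f - fg_old)[observed].max(initial=0.0),
                        np.abs(v_o - vo_g).max(initial=0.0),
                        np.abs(v_d - vd_g).max(initial=0.0))

        E = (v_o[:, None, None] * n[None, :, None]
             + v_d[:, None, None] * n[None, None, :] + f[None, :, :])
        logq = -E - logsumexp(-E, axis=(1, 2), keepdims=True)
        mask = P > 0
        obj = float((P[mask] * (np.log(P[mask]) - logq[mask])).sum())
        history.append(obj)
        if (abs(prev_obj - obj) < opts.tol_objective
                and max_delta < opts.tol_param):
            converged = True
            prev_obj = obj
            break
        prev_obj = obj

    model = DFFTModel(empirical.grid, L, f, v_o, v_d, meta or {})
    report = FitReport(objective=prev_obj, iterations=it,
                       max_param_change=float(max_delta), converged=converged,
                       objective_history=history)
    return model, report
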