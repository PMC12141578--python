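"""Direct probabilistic (DP) model: per-bin joint density tables.

The DP model stores the full joint probability table P_b(n_o, n_d) for every
bin — 100 x 20 x 20 = 40,000 free probabilities at the defaults — estimated
from (optionally weighted) discretized states with a uniform pseudocount to
keep held-out loglikelihoods finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .density import CourtGrid, DensityState

__all__ = ["DPModel", "fit_dp", "loglik"]


@dataclass
class DPModel:
    """Per-bin joint pmf over (n_o, n_d), shape (n_bins, L, L)."""

    grid: CourtGrid
    n_levels: int
    alpha: float
    table: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        B, L = self.grid.n_bins, self.n_levels
        if self.table.shape != (B, L, L):
            raise ValueError(f"table must have shape {(B, L, L)}")
        sums = self.table.sum(axis=(1, 2))
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each bin's table must sum to 1")
        self._log_table = None

    @property
    def n_parameters(self) -> int:
        return self.grid.n_bins * self.n_levels ** 2

    def log_prob_table(self) -> np.ndarray:
        """(n_bins, L, L) log probabilities; -inf where the pmf is zero."""
        if self._log_table is None:
            with np.errstate(divide="ignore"):
                self._log_table = np.log(self.table)
        return self._log_table

    def save(self, path) -> None:
        header = {"model_type": "dp", "n_levels": self.n_levels,
                  "alpha": self.alpha,
                  "grid": [self.grid.x_min, self.grid.x_max, self.grid.y_min,
                           self.grid.y_max, self.grid.bin_size],
                  "meta": self.meta}
        np.savez(path, header=json.dumps(header), table=self.table)

    @classmethod
    def load(cls, path) -> "DPModel":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header["model_type"] != "dp":
                raise ValueError("not a DP model file")
            grid = CourtGrid(*header["grid"])
            return cls(grid, header["n_levels"], header["alpha"],
                       z["table"], header.get("meta", {}))


def fit_dp(states: Sequence[DensityState], weights=None, alpha: float = 0.1,
           grid: CourtGrid | None = None, n_levels: int = 20,
           meta: dict | None = None) -> DPModel:
    """Weighted per-bin joint frequency tables with pseudocount ``alpha``.

    P_b(s) = (alpha + sum_i w_i [state_i,b == s]) / (L^2 alpha + sum_i w_i).
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one state")
    if grid is None:
        grid = states[0].grid
    B, L = grid.n_bins, n_levels
    if weights is None:
        weights = np.ones(len(states))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(states),):
        raise ValueError("weights must match states in length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")

    # per-bin weighted bincount over flattened (n_o, n_d) codes
    codes = np.stack([s.n_o * L + s.n_d for s in states])  # (S, B)
    counts = np.empty((B, L * L))
    for b in range(B):
        counts[b] = np.bincount(codes[:, b], weights=weights, minlength=L * L)
    table = (counts + alpha) / (L * L * alpha + total)
    table = table.reshape(B, L, L)
    # alpha=0 leaves the normalization exact; renormalize defensively
    table /= table.sum(axis=(1, 2), keepdims=True)
    return DPModel(grid, n_levels, alpha, table, meta or {})


def loglik(model, state: DensityState) -> float:
    """Summed per-bin log probability of a discretized state (Eq.-of-record
    loglikelihood surrogate ln P-tilde = sum_b ln P_b(n_o,b, n_d,b)).

    Works for any model exposing ``log_prob_table()`` (DP or DFFT). Returns
    -inf when the state hits a zero-probability cell (only possible with a
    zero pseudocount).
    """
    lt = model.log_prob_table()
    B = lt.shape[0]
    vals = lt[np.arange(B), state.n_o, state.n_d]
    return float(vals.sum())
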