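"""Hidden-agent localization and outcome scoring/calibration.

Two efficacy operations built on the fitted density models:

* **Localization** — with one defender removed from a frame, scan a fine
  candidate grid over the half-court (0.5 ft spacing by default), insert the
  missing agent at each candidate cell, rebuild the discretized state, and
  evaluate the summed per-bin loglikelihood. The top-q area of the resulting
  map is the model's prediction for where the hidden defender stands.

* **Scoring/calibration** — evaluate a frame's loglikelihood under models
  conditioned on different play outcomes; the differences (e.g.
  ln P~_{R=2} - ln P~_{R=0}) are binned against realized binary outcomes and
  summarized by a least-squares line whose slope is reported in percentage
  points per unit loglikelihood difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .density import (CourtGrid, DiscretizationRule, Frame,
                      calibrate_discretization, compute_density)
from .dp import loglik

__all__ = ["LikelihoodMap", "TopRegion", "CalibrationCurve", "ScoreResult",
           "locate_hidden", "top_region", "localization_quantile",
           "outcome_score", "calibrate"]


@dataclass
class LikelihoodMap:
    """ln P~ evaluated at every candidate cell center of a fine scan grid."""

    grid: CourtGrid
    step: float
    x_centers: np.ndarray    # (n_cx,)
    y_centers: np.ndarray    # (n_cy,)
    loglik: np.ndarray       # (n_cy, n_cx)
    model: object = None

    @property
    def n_cells(self) -> int:
        return self.loglik.size

    def cell_of(self, xy) -> tuple[int, int]:
        """(row, col) of the cell whose center is nearest to ``xy``."""
        x, y = float(xy[0]), float(xy[1])
        col = int(np.clip(round((x - self.x_centers[0]) / self.step), 0,
                          len(self.x_centers) - 1))
        row = int(np.clip(round((y - self.y_centers[0]) / self.step), 0,
                          len(self.y_centers) - 1))
        return row, col

    def argmax(self) -> tuple[int, int]:
        r, c = np.unravel_index(np.argmax(self.loglik), self.loglik.shape)
        return int(r), int(c)

    def _order(self) -> np.ndarray:
        """Flat cell indices sorted by decreasing ln P~, ties by (row, col)."""
        ll = self.loglik.ravel()
        rows, cols = np.divmod(np.arange(ll.size), self.loglik.shape[1])
        return np.lexsort((cols, rows, -ll))


@dataclass
class TopRegion:
    """The most-likely fraction ``q`` of the half-court area for a map."""

    map: LikelihoodMap
    q: float
    cells: np.ndarray  # (k,) flat indices, ordered most to least likely

    def __len__(self):
        return len(self.cells)

    def contains(self, xy) -> bool:
        r, c = self.map.cell_of(xy)
        return bool(np.isin(r * self.map.loglik.shape[1] + c, self.cells))

    def cell_coords(self) -> np.ndarray:
        """(k, 2) coordinates of member cell centers."""
        rows, cols = np.divmod(self.cells, self.map.loglik.shape[1])
        return np.column_stack([self.map.x_centers[cols],
                                self.map.y_centers[rows]])


@dataclass
class ScoreResult:
    """Loglikelihood of one frame under each conditioned model."""

    logliks: dict
    differences: dict = field(default_factory=dict)

    def diff(self, a, b) -> float:
        """ln P~ under model ``a`` minus under model ``b``."""
        return self.logliks[a] - self.logliks[b]


@dataclass
class CalibrationCurve:
    """Binned outcome fractions vs loglikelihood difference, plus the
    least-squares line through the surviving bin means."""

    bin_centers: np.ndarray
    fractions: np.ndarray   # outcome fraction per surviving bin
    counts: np.ndarray
    slope: float            # percentage points per unit delta ln P~
    intercept: float        # percentage points at delta ln P~ = 0
    pearson_r: float


def locate_hidden(frame: Frame, model, step: float = 0.5,
                  sigma: float = 5.0,
                  rule: DiscretizationRule | None = None,
                  hidden_group: str = "defense") -> LikelihoodMap:
    """Likelihood scan for one missing agent over a half-foot candidate grid.

    ``frame`` must carry the 5 agents of the complete group and 4 of the
    group the hidden agent belongs to. The scan is deterministic and exactly
    independent of candidate evaluation order: the fixed 9-agent density
    contribution is computed once and the candidate's bin-mass vector is
    added incrementally per cell.
    """
    grid = model.grid
    if rule is None:
        rule = calibrate_discretization(grid, sigma, model.n_levels)
    if hidden_group == "defense":
        fixed_partial, complete = frame.defense, frame.offense
    elif hidden_group == "offense":
        fixed_partial, complete = frame.offense, frame.defense
    else:
        raise ValueError("hidden_group must be 'offense' or 'defense'")
    fixed_partial = np.asarray(fixed_partial, float).reshape(-1, 2)
    complete = np.asarray(complete, float).reshape(-1, 2)
    if complete.shape[0] != 5 or fixed_partial.shape[0] != 4:
        raise ValueError("need 5 agents in the complete group and 4 in the "
                         "group with the hidden agent")

    base_partial = compute_density(fixed_partial, grid, sigma).values
    n_complete = np.asarray(
        np.minimum(np.floor(compute_density(complete, grid, sigma).values
                            / rule.delta + 0.5 + 1e-9), rule.clip_max),
        dtype=np.intp)

    # candidate cell centers
    xc = np.arange(grid.x_min + step / 2, grid.x_max, step)
    yc = np.arange(grid.y_min + step / 2, grid.y_max, step)
    # 1-D Gaussian masses of a candidate agent per grid bin
    dx = np.diff(ndtr((grid.x_edges[None, :] - xc[:, None]) / sigma), axis=1)
    dy = np.diff(ndtr((grid.y_edges[None, :] - yc[:, None]) / sigma), axis=1)

    base2d = base_partial.reshape(grid.n_y, grid.n_x)
    # (n_cy, n_cx, n_y, n_x): partial-group density with the candidate added
    dens = (base2d[None, None, :, :]
            + dy[:, None, :, None] * dx[None, :, None, :])
    levels = np.minimum(np.floor(dens / rule.delta + 0.5 + 1e-9),
                        rule.clip_max).astype(np.intp)
    levels = levels.reshape(len(yc), len(xc), grid.n_bins)

    lt = model.log_prob_table()  # (B, L, L)
    B = grid.n_bins
    if hidden_group == "defense":
        cond = lt[np.arange(B), n_complete, :]      # (B, L) over n_d
    else:
        cond = np.transpose(lt, (0, 2, 1))[np.arange(B), n_complete, :]
    ll = cond[np.arange(B)[None, None, :], levels].sum(axis=2)
    return LikelihoodMap(grid, step, xc, yc, ll, model)


def top_region(map: LikelihoodMap, q: float) -> TopRegion:
    """Top ceil(q * N) cells of the map by ln P~ (ties by row, column)."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    k = int(np.ceil(q * map.n_cells))
    return TopRegion(map, q, map._order()[:k])


def localization_quantile(map: LikelihoodMap, true_location) -> float:
    """Smallest area fraction q whose top region contains the true location."""
    r, c = map.cell_of(true_location)
    flat = r * map.loglik.shape[1] + c
    order = map._order()
    rank = int(np.nonzero(order == flat)[0][0])
    return (rank + 1) / map.n_cells


def outcome_score(frame: Frame, models: dict, sigma: float = 5.0,
                  rule: DiscretizationRule | None = None) -> ScoreResult:
    """Eq.-1 loglikelihood of a frame under each conditioned model, plus all
    pairwise differences (antisymmetric under model swap)."""
    from .density import frame_to_state
    logliks = {}
    for name, model in models.items():
        if rule is None:
            rule = calibrate_discretization(model.grid, sigma, model.n_levels)
        state = frame_to_state(frame, model.grid, sigma, rule)
        logliks[name] = loglik(model, state)
    names = list(logliks)
    diffs = {(a, b): logliks[a] - logliks[b]
             for i, a in enumerate(names) for b in names[i + 1:]}
    return ScoreResult(logliks, diffs)


def calibrate(scores, outcomes, bin_width: float = 2.0,
              min_count: int = 50) -> CalibrationCurve:
    """Binned outcome fractions against scores, with a least-squares line.

    Bins of width ``bin_width`` span the observed score range; bins with
    fewer than ``min_count`` samples are dropped. The slope is in percentage
    points of outcome probability per unit score; ``pearson_r`` is computed
    over the surviving bin means.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have equal length")
    lo = np.floor(scores.min() / bin_width) * bin_width
    hi = np.ceil(scores.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 3:
        edges = np.array([lo, (lo + hi) / 2, hi])
    idx = np.clip(np.digitize(scores, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=outcomes, minlength=len(edges) - 1)
    keep = counts >= min_count
    if keep.sum() < 2:
        raise ValueError("fewer than 2 bins survive min_count; widen bins "
                         "or lower min_count")
    centers = ((edges[:-1] + edges[1:]) / 2)[keep]
    fracs = sums[keep] / counts[keep]
    slope, intercept = np.polyfit(centers, 100.0 * fracs, 1)
    r = float(stats.pearsonr(centers, fracs)[0]) if len(centers) > 1 else np.nan
    return CalibrationCurve(centers, fracs, counts[keep], float(slope),
                            float(intercept), r)
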