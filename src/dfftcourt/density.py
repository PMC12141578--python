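"""Court geometry, Gaussian player-density fields, and density discretization.

Continuous agent coordinates are turned into per-bin expected counts by
integrating a unit isotropic 2-D Gaussian (sigma = 5 ft by default) over each
bin of a fixed half-court grid, then discretized to integer density levels.
The discretization is calibrated so that a single agent standing at the exact
center of an interior bin produces level 7 in that bin, and levels clip at
``n_levels - 1`` (three coincident agents reach the cap).

Coordinate convention: x runs sideline to sideline in [-25, 25] ft, y runs
from the half-court line (y = 0) toward the baseline (y = 50); the offense
attacks the y = 50 end and the hoop sits at (0, 41.75). The 50 ft grid extent
overhangs the 47 ft physical half-court by 3 ft at the baseline end, which
keeps a clean 10x10 grid of 5x5 ft bins.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "HOOP",
    "CourtGrid",
    "Frame",
    "DensityField",
    "DensityState",
    "DiscretizationRule",
    "PipelineConfig",
    "compute_density",
    "calibrate_discretization",
    "discretize",
    "frame_to_state",
    "inside_three_point_arc",
]

#: Hoop location (ft) in the package coordinate convention.
HOOP = (0.0, 41.75)

#: 3-point arc radius from the hoop (ft) and the corner-three line |x| (ft).
ARC_RADIUS = 23.75
CORNER_X = 22.0


def inside_three_point_arc(x, y) -> np.ndarray | bool:
    """True where (x, y) lies inside the 3-point line (2-point territory).

    The boundary is the 23.75 ft arc centered on the hoop, truncated by the
    22 ft corner lines below the break.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x - HOOP[0], y - HOOP[1])
    out = (r < ARC_RADIUS) & (np.abs(x) < CORNER_X)
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CourtGrid:
    """A rectangular grid of square bins covering the half-court.

    Bins are indexed row-major: ``b = iy * n_x + ix`` with ``ix`` increasing
    with x and ``iy`` with y.
    """

    x_min: float = -25.0
    x_max: float = 25.0
    y_min: float = 0.0
    y_max: float = 50.0
    bin_size: float = 5.0

    def __post_init__(self):
        for span, lo, hi in ((self.x_max - self.x_min, self.x_min, self.x_max),
                             (self.y_max - self.y_min, self.y_min, self.y_max)):
            if hi <= lo:
                raise ValueError("grid bounds must satisfy min < max")
            n = span / self.bin_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"grid span {span} is not an integer multiple of "
                    f"bin_size {self.bin_size}")

    @property
    def n_x(self) -> int:
        return int(round((self.x_max - self.x_min) / self.bin_size))

    @property
    def n_y(self) -> int:
        return int(round((self.y_max - self.y_min) / self.bin_size))

    @property
    def n_bins(self) -> int:
        return self.n_x * self.n_y

    @property
    def x_edges(self) -> np.ndarray:
        return self.x_min + self.bin_size * np.arange(self.n_x + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y_min + self.bin_size * np.arange(self.n_y + 1)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + self.bin_size * (np.arange(self.n_x) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + self.bin_size * (np.arange(self.n_y) + 0.5)

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 2) array of bin-center coordinates, row-major order."""
        X, Y = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([X.ravel(), Y.ravel()])

    def bin_index(self, x, y) -> np.ndarray:
        """Map coordinates to flat bin indices (clipped to the grid)."""
        ix = np.clip(((np.asarray(x) - self.x_min) // self.bin_size).astype(int),
                     0, self.n_x - 1)
        iy = np.clip(((np.asarray(y) - self.y_min) // self.bin_size).astype(int),
                     0, self.n_y - 1)
        return iy * self.n_x + ix

    def contains(self, x, y) -> np.ndarray | bool:
        out = ((np.asarray(x) >= self.x_min) & (np.asarray(x) <= self.x_max)
               & (np.asarray(y) >= self.y_min) & (np.asarray(y) <= self.y_max))
        return bool(out) if np.ndim(out) == 0 else out


@dataclass
class Frame:
    """One time-slice of a play: 5 offense + 5 defense agents and the ball.

    ``outcome`` is the play result R in {0, 2, 3}: 0 means the defense
    prevented the score, 2/3 the points the offense obtained.
    """

    play_id: object
    t_to_shot: float
    offense: np.ndarray  # (5, 2) ft
    defense: np.ndarray  # (5, 2) ft
    ball: np.ndarray     # (2,) ft
    outcome: int | None = None
    timestamp: float | None = None

    def __post_init__(self):
        self.offense = np.asarray(self.offense, dtype=float)
        self.defense = np.asarray(self.defense, dtype=float)
        self.ball = np.asarray(self.ball, dtype=float)
        if self.offense.shape != (5, 2) or self.defense.shape != (5, 2):
            raise ValueError("each group must contain exactly 5 agents")
        if self.ball.shape != (2,):
            raise ValueError("ball must be a single (x, y) point")
        if self.outcome is not None and self.outcome not in (0, 2, 3):
            raise ValueError(f"outcome must be in {{0, 2, 3}}, got {self.outcome}")


@dataclass
class DensityField:
    """Continuous per-bin expected agent counts for one group."""

    grid: CourtGrid
    values: np.ndarray  # (n_bins,)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("values must have one entry per bin")


@dataclass
class DensityState:
    """Discretized offensive/defensive density levels, one pair per bin."""

    grid: CourtGrid
    n_o: np.ndarray  # (n_bins,) int
    n_d: np.ndarray  # (n_bins,) int

    def __post_init__(self):
        self.n_o = np.asarray(self.n_o, dtype=np.intp)
        self.n_d = np.asarray(self.n_d, dtype=np.intp)
        if self.n_o.shape != (self.grid.n_bins,) or self.n_d.shape != (self.grid.n_bins,):
            raise ValueError("level arrays must have one entry per bin")


@dataclass(frozen=True)
class DiscretizationRule:
    """Linear level map: level = min(clip_max, round(value / delta)).

    ``delta`` is chosen so a single agent at an interior bin center lands
    exactly on level 7; rounding is half-away-from-zero with a tiny guard
    against floating-point ties.
    """

    n_levels: int = 20
    delta: float = 0.0

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    @property
    def clip_max(self) -> int:
        return self.n_levels - 1


def _bin_masses(points: np.ndarray, edges: np.ndarray, sigma: float) -> np.ndarray:
    """(n_agents, n_bins_1d) Gaussian mass of each agent in each 1-D bin."""
    z = (edges[None, :] - points[:, None]) / sigma
    cdf = ndtr(z)
    return np.diff(cdf, axis=1)


def compute_density(agents, grid: CourtGrid, sigma: float = 5.0) -> DensityField:
    """Sum of unit 2-D Gaussians integrated over each bin rectangle.

    Each agent contributes its Gaussian probability mass inside every bin
    (an expected count, additive over agents); mass outside the grid is
    discarded.

    Parameters
    ----------
    agents
        Sequence of (x, y) points; may be empty.
    sigma
        Gaussian standard deviation in feet.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.asarray(list(agents) if not isinstance(agents, np.ndarray) else agents,
                     dtype=float)
    if pts.size == 0:
        return DensityField(grid, np.zeros(grid.n_bins))
    pts = pts.reshape(-1, 2)
    if not np.all(np.isfinite(pts)):
        raise ValueError("agent coordinates must be finite")
    mx = _bin_masses(pts[:, 0], grid.x_edges, sigma)  # (k, n_x)
    my = _bin_masses(pts[:, 1], grid.y_edges, sigma)  # (k, n_y)
    # mass per bin (iy, ix) summed over agents, flattened row-major
    values = np.einsum("ky,kx->yx", my, mx).ravel()
    return DensityField(grid, values)


def calibrate_discretization(grid: CourtGrid, sigma: float = 5.0,
                             n_levels: int = 20) -> DiscretizationRule:
    """Fix the linear level map from the single-agent-at-center anchor.

    The bin-integrated mass ``c1`` of one agent at an interior bin center is
    pinned to level 7, so ``delta = c1 / 7``.
    """
    h = grid.bin_size / (2.0 * sigma)
    c1 = float((ndtr(h) - ndtr(-h)) ** 2)
    return DiscretizationRule(n_levels=n_levels, delta=c1 / 7.0)


def discretize(field: DensityField | np.ndarray, rule: DiscretizationRule) -> np.ndarray:
    """Map continuous densities to integer levels in [0, clip_max]."""
    values = field.values if isinstance(field, DensityField) else np.asarray(field)
    # round half away from zero (values are nonnegative) with a tie guard
    levels = np.floor(values / rule.delta + 0.5 + 1e-9).astype(np.intp)
    return np.minimum(levels, rule.clip_max)


@dataclass(frozen=True)
class PipelineConfig:
    """Grid and discretization parameters as one configurable block.

    Loadable from YAML or JSON; keys are ``sigma_ft, bin_ft, nx, ny,
    n_levels`` with the package defaults below.
    """

    sigma_ft: float = 5.0
    bin_ft: float = 5.0
    nx: int = 10
    ny: int = 10
    n_levels: int = 20

    def grid(self) -> CourtGrid:
        half_x = self.nx * self.bin_ft / 2.0
        return CourtGrid(x_min=-half_x, x_max=half_x, y_min=0.0,
                         y_max=self.ny * self.bin_ft, bin_size=self.bin_ft)

    def rule(self) -> DiscretizationRule:
        return calibrate_discretization(self.grid(), self.sigma_ft,
                                        self.n_levels)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml  # parses JSON too (JSON is a YAML subset)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def frame_to_state(frame: Frame, grid: CourtGrid, sigma: float = 5.0,
                   rule: DiscretizationRule | None = None) -> DensityState:
    """Per-group density computation + discretization for one frame.

    Same-group agents are exchangeable: permuting them leaves the state
    unchanged.
    """
    if rule is None:
        rule = calibrate_discretization(grid, sigma)
    n_o = discretize(compute_density(frame.offense, grid, sigma), rule)
    n_d = discretize(compute_density(frame.defense, grid, sigma), rule)
    return DensityState(grid, n_o, n_d)
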