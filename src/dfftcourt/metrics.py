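"""Agent-specific metrics: defensive positioning gain and player gravity.

*Defensive gain* asks whether a specific defender stands in spots that help
the whole defense: per play (at shot time), the defender is removed, the
most-likely 10% of the half-court for a typical defender is built from the
successful-defense model, plays where the defender stands outside that
region are dropped (atypical plays), and the retained plays contribute the
loglikelihood difference D = ln P~_{R=0} - ln P~_{R=r} at the actual spot
minus the region average of D.

*Gravity* quantifies how strongly an offensive player attracts the defense,
deconfounded from teammate positioning: a model conditioned on that player
occupying an anchor location is compared against a model conditioned on
*any* offensive player occupying it, with both evaluated on the **same**
offensive configurations, so differences in the predicted local (9-bin)
defensive density are attributable to the player's identity alone. Values
are reported in *ball equivalents*: a per-anchor linear rescaling placing
the typical player's off-ball local density at 0.00 and on-ball at 1.00.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from .density import (CourtGrid, DensityState, DiscretizationRule, Frame,
                      calibrate_discretization, frame_to_state)
from .dfft import (FitOptions, conditional_defense,
                   conditional_defense_means, fit_dfft)
from .dp import fit_dp
from .inference import locate_hidden, top_region
from .io import TrackingTable

__all__ = ["DefensiveGainReport", "GravityResult", "defensive_gain",
           "points_saved", "local_defense_density", "gravity", "occupancy",
           "drop_defender"]


@dataclass
class DefensiveGainReport:
    player_id: object
    gain: float
    n_positions: int
    retained_fraction: float
    contributions: np.ndarray = field(repr=False, default=None)


@dataclass
class GravityResult:
    player_id: object
    anchor: tuple
    off_ball: float          # ball equivalents; NaN if unavailable
    on_ball: float
    off_available: bool
    on_available: bool
    n_frames: dict
    # per-eval-frame paired differences (player - typical), in raw local
    # density units, for uncertainty estimation by the caller
    paired_diff_off: np.ndarray = field(repr=False, default=None)
    paired_diff_on: np.ndarray = field(repr=False, default=None)
    scale: float = np.nan    # typical on-ball minus off-ball local density


def drop_defender(frame: Frame, index: int) -> SimpleNamespace:
    """Frame-like view with one defender removed (for localization scans)."""
    keep = [i for i in range(len(frame.defense)) if i != index]
    return SimpleNamespace(offense=frame.offense,
                           defense=frame.defense[keep])


def defensive_gain(player_id, table: TrackingTable, model_R0, model_Rr,
                   q: float = 0.10, step: float = 0.5, sigma: float = 5.0,
                   rule: DiscretizationRule | None = None) -> DefensiveGainReport:
    """Mean loglikelihood-difference advantage of a defender's actual spots.

    ``table`` should already be restricted to the frames of interest
    (typically shot-time frames of plays with the relevant outcome, with the
    player on defense). Frames where the player stands outside the top-q
    region for a typical defender (built from ``model_R0``) are skipped.
    """
    contributions = []
    n_seen = 0
    for fr, pos in _frames_with_player(table, "defense", player_id):
        n_seen += 1
        idx = int(np.argmin(((fr.defense - pos) ** 2).sum(axis=1)))
        partial = drop_defender(fr, idx)
        map0 = locate_hidden(partial, model_R0, step, sigma, rule)
        region = top_region(map0, q)
        if not region.contains(pos):
            continue
        mapr = locate_hidden(partial, model_Rr, step, sigma, rule)
        D = map0.loglik - mapr.loglik
        r, c = map0.cell_of(pos)
        region_mean = D.ravel()[region.cells].mean()
        contributions.append(D[r, c] - region_mean)
    if not contributions:
        raise ValueError("no frames retained by the region filter")
    contributions = np.asarray(contributions)
    return DefensiveGainReport(player_id, float(contributions.mean()),
                               len(contributions),
                               len(contributions) / n_seen, contributions)


def points_saved(gain_2: float, gain_3: float, slope_2: float, slope_3: float,
                 n2: int = 60, n3: int = 30) -> float:
    """Approximate points saved per game from positioning gains.

    Converts each gain through the calibration slope (percentage points of
    scoring probability per unit loglikelihood difference) at the stated
    2-point and 3-point attempt volumes.
    """
    return (n2 * (slope_2 * gain_2 / 100.0) * 2.0
            + n3 * (slope_3 * gain_3 / 100.0) * 3.0)


def _block_bins(grid: CourtGrid, center_bin: int) -> np.ndarray:
    iy, ix = divmod(int(center_bin), grid.n_x)
    bins = [jy * grid.n_x + jx
            for jy in range(max(iy - 1, 0), min(iy + 2, grid.n_y))
            for jx in range(max(ix - 1, 0), min(ix + 2, grid.n_x))]
    return np.asarray(bins)


def local_defense_density(state_or_model, center_bin: int,
                          n_o: np.ndarray | None = None) -> float:
    """Mean defensive density over the 3x3 bin block around ``center_bin``
    (a 15 x 15 ft square; edge bins average over existing neighbors only).

    For a :class:`DensityState` this is the mean observed level; for a
    reduced model it is the mean conditional expectation E[n_d | n_o] given
    the frame's offensive levels ``n_o``.
    """
    if isinstance(state_or_model, DensityState):
        bins = _block_bins(state_or_model.grid, center_bin)
        return float(state_or_model.n_d[bins].mean())
    model = state_or_model
    if n_o is None:
        raise ValueError("a model evaluation needs the frame's offensive levels")
    bins = _block_bins(model.grid, center_bin)
    means = [conditional_defense(model, int(b), int(n_o[b]))[1] for b in bins]
    return float(np.mean(means))


def _frames_with_player(table: TrackingTable, object_class: str, player_id):
    """Yield (Frame, player_xy) for frames where the player appears."""
    df = table.df
    has = df[(df.object_class == object_class) & (df.agent_id == player_id)]
    keys = set(zip(has.play_id, has.frame_index))
    pos_lookup = {(p, f): (x, y) for p, f, x, y
                  in zip(has.play_id, has.frame_index, has.x, has.y)}
    frame_ids = df[["play_id", "frame_index"]].drop_duplicates()
    frame_iter = table.frames()
    for (_, row), fr in zip(frame_ids.sort_values(
            ["play_id", "frame_index"]).iterrows(), frame_iter):
        key = (fr.play_id, row["frame_index"])
        if key in keys:
            yield fr, np.asarray(pos_lookup[key], float)


def occupancy(player_id, anchors, table: TrackingTable,
              radius: float = 5.0, object_class: str = "offense") -> np.ndarray:
    """Fraction of the player's frames spent within ``radius`` of each anchor."""
    df = table.df
    rows = df[(df.object_class == object_class) & (df.agent_id == player_id)]
    pos = rows[["x", "y"]].to_numpy(dtype=float)
    anchors = np.asarray(anchors, float).reshape(-1, 2)
    if len(pos) == 0:
        return np.zeros(len(anchors))
    d = np.linalg.norm(pos[:, None, :] - anchors[None, :, :], axis=2)
    return (d <= radius).mean(axis=0)


#: Default gravity anchor locations (ft): rim, posts, top of key, wings,
#: corners.
DEFAULT_GRAVITY_ANCHORS = np.array([
    (0.0, 39.0), (-8.0, 37.5), (8.0, 37.5), (0.0, 22.0),
    (-16.0, 24.0), (16.0, 24.0), (-22.0, 44.0), (22.0, 44.0)])


def gravity(player_id, anchor, table: TrackingTable, radius: float = 5.0,
            onball_thresh: float = 3.0, min_frames: int = 500,
            sigma: float = 5.0, n_levels: int = 20, alpha: float = 1e-3,
            fit_opts: FitOptions | None = None,
            grid: CourtGrid | None = None) -> GravityResult:
    """Local gravity of one offensive player at one anchor, in ball
    equivalents.

    Four conditionings are fitted (player/typical x off-ball/on-ball, by
    whether the anchor occupant is within ``onball_thresh`` ft of the ball),
    and all are evaluated on the same offensive configurations — every frame
    with any offensive agent within ``radius`` of the anchor. A subset
    smaller than ``min_frames`` marks the corresponding value unavailable
    (NaN) rather than fabricating it.

    The empirical tables behind these fits use a near-zero pseudocount: a
    uniform pseudocount drags each subset toward the uniform state table in
    inverse proportion to its size, which inflates the expected defensive
    level of small (player-specific) subsets relative to large (typical)
    ones and biases the player-minus-typical contrast (about +1 ball
    equivalent at alpha = 0.1 with few hundred-frame subsets).
    """
    if grid is None:
        grid = CourtGrid()
    anchor = np.asarray(anchor, float)
    rule = calibrate_discretization(grid, sigma, n_levels)
    anchor_bin = int(grid.bin_index(anchor[0], anchor[1]))

    # classify frames
    subsets = {"p_off": [], "p_on": [], "t_off": [], "t_on": []}
    eval_states = []
    df = table.df
    prows = df[(df.object_class == "offense") & (df.agent_id == player_id)]
    ppos = {(p, f): (x, y) for p, f, x, y
            in zip(prows.play_id, prows.frame_index, prows.x, prows.y)}
    fi_keys = (df[["play_id", "frame_index"]].drop_duplicates()
               .sort_values(["play_id", "frame_index"]))
    for (_, row), fr in zip(fi_keys.iterrows(), table.frames()):
        d_any = np.linalg.norm(fr.offense - anchor, axis=1)
        occ = int(np.argmin(d_any))
        state = None
        if d_any[occ] <= radius:
            state = frame_to_state(fr, grid, sigma, rule)
            eval_states.append(state)
            onball = np.linalg.norm(fr.offense[occ] - fr.ball) <= onball_thresh
            subsets["t_on" if onball else "t_off"].append(state)
        key = (fr.play_id, row["frame_index"])
        if key in ppos:
            pxy = np.asarray(ppos[key], float)
            if np.linalg.norm(pxy - anchor) <= radius:
                if state is None:
                    state = frame_to_state(fr, grid, sigma, rule)
                onball = np.linalg.norm(pxy - fr.ball) <= onball_thresh
                subsets["p_on" if onball else "p_off"].append(state)

    n_frames = {k: len(v) for k, v in subsets.items()}
    models = {}
    for key, states in subsets.items():
        if len(states) >= min_frames:
            emp = fit_dp(states, alpha=alpha, grid=grid, n_levels=n_levels)
            models[key], _ = fit_dfft(emp, fit_opts)

    block = _block_bins(grid, anchor_bin)

    def eval_model(m):
        means = conditional_defense_means(m)  # (B, L)
        return np.array([means[block, s.n_o[block]].mean()
                         for s in eval_states])

    off_avail = "p_off" in models and "t_off" in models and "t_on" in models
    on_avail = "p_on" in models and "t_off" in models and "t_on" in models
    g_off = g_on = np.nan
    diff_off = diff_on = None
    scale = np.nan
    if "t_off" in models and "t_on" in models:
        v_t_off = eval_model(models["t_off"])
        v_t_on = eval_model(models["t_on"])
        scale = float(v_t_on.mean() - v_t_off.mean())
        if off_avail:
            v_p_off = eval_model(models["p_off"])
            diff_off = v_p_off - v_t_off
            g_off = float(diff_off.mean() / scale)
        if on_avail:
            v_p_on = eval_model(models["p_on"])
            diff_on = v_p_on - v_t_off
            g_on = float(diff_on.mean() / scale)
    return GravityResult(player_id, tuple(anchor), g_off, g_on,
                         off_avail, on_avail, n_frames,
                         diff_off, diff_on, scale)
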