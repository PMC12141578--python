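"""Synthetic generators with the statistical structure the inference assumes.

Everything here is fully determined by (spec, seed). Three layers:

* ``sample_states`` draws per-bin (n_o, n_d) pairs independently from a
  ground-truth reduced model — the exact-recovery harness, since the fit
  treats bins independently.
* ``sample_frames`` runs a Metropolis-Hastings chain over the 10 agents'
  continuous coordinates with target density exp(-H), where H is the
  ground-truth bin energy evaluated through the density pipeline plus smooth
  agent-level terms (defender attraction to the ball, scripted player
  effects). This exercises the full pipeline and deliberately introduces
  bin-to-bin correlation the reduced model does not represent.
* ``assign_outcomes`` attaches play outcomes whose success log-odds are
  linear in a documented configuration score (scaled negative local
  defensive density at the ball), so calibration recovery has a known
  generative line.

The default truth emulates half-court offense: both groups prefer the rim
area, the offense also populates the 3-point arc, and the interaction
function couples the two groups' densities positively (defense tracks
offense). It does not emulate play choreography (screens, cuts) or shot-clock
dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, ndtr

from .density import (HOOP, CourtGrid, DensityState, DiscretizationRule,
                      Frame, calibrate_discretization,
                      inside_three_point_arc)
from .dfft import DFFTModel
from .io import BallAnchorSet, TrackingTable

__all__ = ["TruthSpec", "OutcomeLink", "PlayerEffect", "MCMCOptions",
           "default_truth", "sample_states", "sample_frames",
           "assign_outcomes", "inject_player_effect", "configuration_score"]


@dataclass(frozen=True)
class OutcomeLink:
    """Logistic outcome link: P(success) = expit(intercept + beta * s).

    ``slope_pct`` is the local slope of the success probability at the
    operating point, in percentage points per unit score (beta = 4 *
    slope_pct / 100, the logistic derivative at p = 1/2). The configuration
    score s is ``score_scale * (score_center - local defensive density at
    the ball)``: crowding the shooter lowers the success odds.

    With ``form="linear"`` the link is instead the straight line
    P(success) = base + (slope_pct / 100) * s, clipped to (0.001, 0.999) —
    the exactly-linear regime a binned calibration should recover.
    """

    intercept: float = 0.0
    slope_pct: float = 2.0
    score_scale: float = 3.0
    score_center: float = 2.0
    form: str = "logistic"
    base: float = 0.45

    @property
    def beta(self) -> float:
        return 4.0 * self.slope_pct / 100.0

    def probability(self, scores) -> np.ndarray:
        s = np.asarray(scores, float)
        if self.form == "linear":
            return np.clip(self.base + self.slope_pct / 100.0 * s,
                           0.001, 0.999)
        return expit(self.intercept + self.beta * s)


@dataclass(frozen=True)
class PlayerEffect:
    """Scripted agent-specific deviation from the typical truth.

    kinds: ``magnet`` (the nearest defender's energy is lowered by a
    Gaussian bump that follows the flagged offensive agent — scripted
    primary-defender attention), ``rim_protector`` (flagged
    defender attracted to the rim whenever the ball is inside the arc),
    ``null_twin`` (no deviation; deconfounding null), ``tether`` (flagged
    offensive agent attracted to a buddy teammate — used to script worlds
    where a non-magnet always stands next to a magnet), ``spot_up``
    (flagged offensive agent personally prefers the 3-point arc ring — a
    shooter's positional profile, independent of any defender effect).
    """

    kind: str
    magnitude: float = 0.0
    agent: int = 0
    buddy: int = 1
    sigma: float = 5.0

    def __post_init__(self):
        if self.kind not in ("magnet", "rim_protector", "null_twin", "tether",
                             "spot_up"):
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class MCMCOptions:
    burn_in: int = 2000        # sweeps before the first kept frame
    thin: int = 20             # sweeps between kept frames
    play_gap: int = 50         # re-equilibration sweeps after a ball switch
    proposal_sigma: float = 2.0
    jump_prob: float = 0.15    # chance of a court-wide relocation proposal
                               # (symmetric mixture; speeds label mixing)
    adapt: bool = True
    target_accept: float = 0.3
    frame_dt: float = 0.25     # seconds between kept frames


@dataclass(frozen=True)
class TruthSpec:
    """Ground-truth world: a reduced density model plus agent-level terms."""

    grid: CourtGrid
    sigma: float
    n_levels: int
    f: np.ndarray
    v_o: np.ndarray
    v_d: np.ndarray
    link: OutcomeLink = OutcomeLink()
    ball_attraction: float = 3.0   # defender energy depth toward the ball
    ball_attr_sigma: float = 3.5
    p_onball: float = 0.8          # chance the ball is carried vs free
    effects: tuple = ()

    def model(self) -> DFFTModel:
        return DFFTModel(self.grid, self.n_levels, self.f.copy(),
                         self.v_o.copy(), self.v_d.copy(),
                         {"source": "truth"})

    def rule(self) -> DiscretizationRule:
        return calibrate_discretization(self.grid, self.sigma, self.n_levels)


def _gauss_bump(centers: np.ndarray, at, width: float) -> np.ndarray:
    d2 = ((centers - np.asarray(at, float)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * width ** 2))


def default_truth(grid: CourtGrid | None = None, sigma: float = 5.0,
                  n_levels: int = 20, link: OutcomeLink | None = None) -> TruthSpec:
    """Half-court-like ground truth.

    The interaction function has quadratic self-terms (keeping typical bin
    levels near 2, matching five agents' Gaussian mass spread over the grid)
    and a positive offense-defense coupling; the potentials carry defensive
    attraction at the rim and offensive attraction at the rim and along the
    3-point arc.
    """
    if grid is None:
        grid = CourtGrid()
    L = n_levels
    n = np.arange(L, dtype=float)
    no, nd = np.meshgrid(n, n, indexing="ij")
    f = 0.06 * no ** 2 + 0.06 * nd ** 2 - 0.035 * no * nd
    f -= f[0, 0]

    centers = grid.bin_centers()
    r_arc = np.abs(np.hypot(centers[:, 0] - HOOP[0], centers[:, 1] - HOOP[1])
                   - 23.75)
    # offense: spacing around the 3-point arc plus rim pressure; defense:
    # packed toward the rim, trailing the offense via the f coupling
    v_o = (-0.45 * _gauss_bump(centers, HOOP, 9.0)
           - 0.60 * np.exp(-r_arc ** 2 / (2 * 5.0 ** 2)))
    v_d = -0.70 * _gauss_bump(centers, HOOP, 10.0)
    v_o -= v_o.mean()
    v_d -= v_d.mean()
    return TruthSpec(grid, sigma, n_levels, f, v_o, v_d,
                     link or OutcomeLink())


def inject_player_effect(spec: TruthSpec, kind: str, magnitude: float,
                         agent: int = 0, buddy: int = 1,
                         sigma: float = 5.0) -> TruthSpec:
    """Return a new TruthSpec with the scripted effect appended.

    Effects compose additively in energy; magnitude 0 is equivalent to
    ``null_twin``.
    """
    eff = PlayerEffect(kind, magnitude, agent, buddy, sigma)
    return replace(spec, effects=spec.effects + (eff,))


# ---------------------------------------------------------------------------
# per-bin independent sampling

def sample_states(truth: TruthSpec, n_draws: int, seed: int) -> list[DensityState]:
    """Draw each bin's (n_o, n_d) independently from the truth model."""
    rng = np.random.default_rng(seed)
    probs = truth.model().prob_table()          # (B, L, L)
    B, L, _ = probs.shape
    codes = np.empty((n_draws, B), dtype=np.intp)
    for b in range(B):
        codes[:, b] = rng.choice(L * L, size=n_draws, p=probs[b].ravel())
    n_o, n_d = np.divmod(codes, L)
    return [DensityState(truth.grid, n_o[i], n_d[i]) for i in range(n_draws)]


# ---------------------------------------------------------------------------
# frame-level Metropolis-Hastings sampler

class _CourtSampler:
    """MH chain over 10 agents' continuous coordinates, target exp(-H)."""

    def __init__(self, truth: TruthSpec, opts: MCMCOptions, rng):
        self.truth = truth
        self.opts = opts
        self.rng = rng
        g = truth.grid
        self.grid = g
        self.rule = truth.rule()
        self.sigma_p = opts.proposal_sigma
        # positions: rows 0-4 offense, 5-9 defense
        self.pos = np.column_stack([
            rng.uniform(g.x_min + 2, g.x_max - 2, 10),
            rng.uniform(g.y_min + 2, g.y_max - 2, 10)])
        self.mass = np.stack([self._agent_mass(self.pos[i]) for i in range(10)])
        self.ball = np.array([0.0, 30.0])
        self.carrier: int | None = None
        self.n_prop = 0
        self.n_acc = 0
        self._E: float | None = None  # cached current-state energy

    def _agent_mass(self, xy) -> np.ndarray:
        g, s = self.grid, self.truth.sigma
        mx = np.diff(ndtr((g.x_edges - xy[0]) / s))
        my = np.diff(ndtr((g.y_edges - xy[1]) / s))
        return np.outer(my, mx).ravel()

    def _levels(self, group_mass_sum) -> np.ndarray:
        return np.minimum(
            np.floor(group_mass_sum / self.rule.delta + 0.5 + 1e-9),
            self.rule.clip_max).astype(np.intp)

    def set_ball(self, carrier: int | None, free_pos=None):
        self.carrier = carrier
        if carrier is None:
            self.ball = np.asarray(free_pos, float)
        else:
            self.ball = self.pos[carrier].copy()
        self._E = None

    def _energy(self, pos, mass) -> float:
        t = self.truth
        n_o = self._levels(mass[:5].sum(axis=0))
        n_d = self._levels(mass[5:].sum(axis=0))
        B = self.grid.n_bins
        H = float(n_o @ t.v_o + n_d @ t.v_d
                  + t.f[n_o, n_d].sum())
        ball = pos[self.carrier] if self.carrier is not None else self.ball
        if t.ball_attraction:
            d2 = ((pos[5:] - ball) ** 2).sum(axis=1)
            H -= t.ball_attraction * np.exp(-d2 / (2 * t.ball_attr_sigma ** 2)).sum()
        for eff in t.effects:
            if eff.kind == "magnet" and eff.magnitude:
                # primary-defender attention: only the nearest defender is
                # drawn in, so the star is not dragged toward packed defense
                d2 = ((pos[5:] - pos[eff.agent]) ** 2).sum(axis=1)
                H -= eff.magnitude * np.exp(-d2.min() / (2 * eff.sigma ** 2))
            elif eff.kind == "rim_protector" and eff.magnitude:
                if inside_three_point_arc(ball[0], ball[1]):
                    d2 = ((pos[5 + eff.agent] - np.asarray(HOOP)) ** 2).sum()
                    H -= eff.magnitude * np.exp(-d2 / (2 * eff.sigma ** 2))
            elif eff.kind == "tether" and eff.magnitude:
                d2 = ((pos[eff.agent] - pos[eff.buddy]) ** 2).sum()
                H -= eff.magnitude * np.exp(-d2 / (2 * eff.sigma ** 2))
            elif eff.kind == "spot_up" and eff.magnitude:
                x, y = pos[eff.agent]
                r_arc = abs(np.hypot(x - HOOP[0], y - HOOP[1]) - 23.75)
                H -= eff.magnitude * np.exp(-r_arc ** 2 / (2 * eff.sigma ** 2))
        return H

    def sweep(self):
        g = self.grid
        if self._E is None:
            self._E = self._energy(self.pos, self.mass)
        for i in self.rng.permutation(10):
            old_xy = self.pos[i].copy()
            if self.rng.random() < self.opts.jump_prob:
                new_xy = np.array([self.rng.uniform(g.x_min, g.x_max),
                                   self.rng.uniform(g.y_min, g.y_max)])
            else:
                new_xy = old_xy + self.rng.normal(0, self.sigma_p, 2)
            self.n_prop += 1
            if not (g.x_min <= new_xy[0] <= g.x_max
                    and g.y_min <= new_xy[1] <= g.y_max):
                continue
            old_mass = self.mass[i].copy()
            old_ball = self.ball.copy()
            self.pos[i] = new_xy
            self.mass[i] = self._agent_mass(new_xy)
            if self.carrier == i:
                self.ball = new_xy.copy()
            new_E = self._energy(self.pos, self.mass)
            if self.rng.random() < np.exp(min(0.0, self._E - new_E)):
                self.n_acc += 1
                self._E = new_E
            else:
                self.pos[i] = old_xy
                self.mass[i] = old_mass
                self.ball = old_ball

    def run(self, n_sweeps: int, adapt: bool = False):
        for k in range(n_sweeps):
            self.sweep()
            if adapt and self.opts.adapt and (k + 1) % 100 == 0:
                rate = self.n_acc / max(self.n_prop, 1)
                self.sigma_p *= float(np.exp(rate - self.opts.target_accept))
                self.sigma_p = float(np.clip(self.sigma_p, 0.2, 10.0))
                self.n_acc = self.n_prop = 0

    @property
    def acceptance_rate(self) -> float:
        return self.n_acc / max(self.n_prop, 1)


def sample_frames(truth: TruthSpec, n_plays: int, frames_per_play: int = 5,
                  mcmc: MCMCOptions | None = None, seed: int = 0,
                  anchors: BallAnchorSet | None = None) -> TrackingTable:
    """Generate a tracking table from one long MH chain.

    Each play fixes the ball for its duration: attached to a randomly chosen
    offensive agent with probability ``p_onball`` (the ball then follows that
    agent), otherwise free at a random anchor location. A short
    re-equilibration gap follows each ball switch. An acceptance rate outside
    [0.05, 0.8] after adaptation triggers a warning.
    """
    if mcmc is None:
        mcmc = MCMCOptions()
    if anchors is None:
        anchors = BallAnchorSet.default()
    rng = np.random.default_rng(seed)
    sampler = _CourtSampler(truth, mcmc, rng)
    sampler.set_ball(None, anchors.points[rng.integers(len(anchors))])
    sampler.run(mcmc.burn_in, adapt=True)
    sampler.n_acc = sampler.n_prop = 0

    frames: list[Frame] = []
    for p in range(n_plays):
        if rng.random() < truth.p_onball:
            sampler.set_ball(int(rng.integers(5)))
        else:
            sampler.set_ball(None, anchors.points[rng.integers(len(anchors))])
        sampler.run(mcmc.play_gap)
        for k in range(frames_per_play):
            sampler.run(mcmc.thin)
            frames.append(Frame(
                play_id=p,
                t_to_shot=(frames_per_play - 1 - k) * mcmc.frame_dt,
                offense=sampler.pos[:5].copy(),
                defense=sampler.pos[5:].copy(),
                ball=sampler.ball.copy(),
                outcome=0))
    rate = sampler.acceptance_rate
    if not 0.05 <= rate <= 0.8:
        warnings.warn(f"MCMC acceptance rate {rate:.3f} outside [0.05, 0.8]",
                      RuntimeWarning, stacklevel=2)
    return TrackingTable.from_frames(frames)


# ---------------------------------------------------------------------------
# outcome assignment

def configuration_score(state: DensityState, ball_bin: int,
                        link: OutcomeLink) -> float:
    """Scaled negative 9-bin local defensive density at the ball."""
    from .metrics import local_defense_density
    local = local_defense_density(state, ball_bin)
    return link.score_scale * (link.score_center - local)


def assign_outcomes(table: TrackingTable, link: OutcomeLink | None = None,
                    seed: int = 0, sigma: float = 5.0,
                    return_scores: bool = False):
    """Assign play outcomes from the shot frame's configuration score.

    Per play, success probability is logistic in the score at the frame
    nearest the shot (smallest t_to_shot); success maps to R = 2 when the
    ball is inside the 3-point arc and R = 3 outside, failure to R = 0.
    """
    from .density import frame_to_state
    if link is None:
        link = OutcomeLink()
    rng = np.random.default_rng(seed)
    grid = CourtGrid()
    rule = calibrate_discretization(grid, sigma)
    shot_frames = {}
    for fr in table.frames():
        cur = shot_frames.get(fr.play_id)
        if cur is None or fr.t_to_shot < cur.t_to_shot:
            shot_frames[fr.play_id] = fr
    records = []
    outcome_by_play = {}
    for pid, fr in shot_frames.items():
        state = frame_to_state(fr, grid, sigma, rule)
        b = int(grid.bin_index(fr.ball[0], fr.ball[1]))
        s = configuration_score(state, b, link)
        p = float(link.probability(s))
        success = rng.random() < p
        if success:
            r = 2 if inside_three_point_arc(fr.ball[0], fr.ball[1]) else 3
        else:
            r = 0
        outcome_by_play[pid] = r
        records.append(dict(play_id=pid, score=s, p_success=p, outcome=r))
    out = TrackingTable.__new__(TrackingTable)
    out.df = table.df.copy()
    out.df["outcome"] = out.df["play_id"].map(outcome_by_play)
    if return_scores:
        import pandas as pd
        return out, pd.DataFrame(records)
    return out
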