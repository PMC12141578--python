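"""Tracking-table ingestion, validation, filters, ball anchors and splits.

The schema is this package's own long format (the raw vendor feeds such
tables are derived from are proprietary): one row per object per frame with
columns ``play_id, frame_index, t_to_shot, object_class, agent_id, x, y,
outcome``. Each frame holds exactly 5 offense + 5 defense agents and one
ball; ``outcome`` is the play result R in {0, 2, 3} repeated on every row of
the play. Coordinates follow the package convention (offense attacks y = 50;
raw full-court data must be reflected per possession before ingestion).

A signed long-axis velocity column ``v_y`` (ft/s, central finite differences
over adjacent frames of the 10-agent mean y, one-sided at play edges) is
computed once at construction on the full play, so the frame filters are
pure per-frame predicates and commute with one another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .density import Frame, inside_three_point_arc

__all__ = ["TrackingTable", "TrackingSchemaError", "BallAnchorSet",
           "read_tracking", "write_tracking", "filter_pre_shot",
           "filter_transition", "ball_weights", "testing_restriction",
           "split_plays"]

COLUMNS = ["play_id", "frame_index", "t_to_shot", "object_class", "agent_id",
           "x", "y", "outcome"]
BALL_ID = "ball"

#: Assumed tracking sample interval (s) when timestamps are degenerate (25 Hz).
DEFAULT_FRAME_INTERVAL = 0.04


class TrackingSchemaError(ValueError):
    """Raised with an itemized list of schema violations."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid tracking table:\n  - " + "\n  - ".join(problems))


def _validate(df: pd.DataFrame) -> list[str]:
    problems = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    bad_class = set(df["object_class"].unique()) - {"offense", "defense", "ball"}
    if bad_class:
        problems.append(f"unknown object_class values: {sorted(bad_class)}")
    bad_outcome = set(df["outcome"].unique()) - {0, 2, 3}
    if bad_outcome:
        problems.append(f"outcome values outside {{0, 2, 3}}: {sorted(bad_outcome)}")
    if (df["t_to_shot"] < 0).any():
        problems.append("negative t_to_shot values")
    if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
        problems.append("non-finite coordinates")
    counts = df.pivot_table(index=["play_id", "frame_index"],
                            columns="object_class", values="x",
                            aggfunc="count", fill_value=0)
    for cls, want in (("offense", 5), ("defense", 5), ("ball", 1)):
        if cls not in counts.columns:
            bad = counts.index
        else:
            bad = counts.index[counts[cls] != want]
        for key in bad[:10]:
            problems.append(f"frame {key}: expected {want} {cls} rows, "
                            f"got {counts.at[key, cls] if cls in counts.columns else 0}")
    n_out = df.groupby("play_id")["outcome"].nunique()
    for pid in n_out.index[n_out > 1][:10]:
        problems.append(f"play {pid}: outcome not constant within play")
    return problems


def _long_axis_velocity(df: pd.DataFrame) -> pd.Series:
    """Signed mean-y velocity per (play, frame), on player rows only."""
    players = df[df["object_class"] != "ball"]
    ybar = (players.groupby(["play_id", "frame_index"])["y"].mean()
            .reset_index().sort_values(["play_id", "frame_index"]))
    t = (df.groupby(["play_id", "frame_index"])["t_to_shot"].first()
         .reset_index().sort_values(["play_id", "frame_index"]))
    ybar = ybar.merge(t, on=["play_id", "frame_index"])
    # elapsed time increases as t_to_shot decreases
    ybar["time"] = -ybar["t_to_shot"]
    out = np.zeros(len(ybar))
    for _, idx in ybar.groupby("play_id").groups.items():
        sub = ybar.loc[idx]
        y = sub["y"].to_numpy()
        tt = sub["time"].to_numpy()
        if len(y) >= 2:
            dt = np.diff(tt)
            dt[dt == 0] = DEFAULT_FRAME_INTERVAL
            tt = np.concatenate([[tt[0]], tt[0] + np.cumsum(dt)])
            v = np.gradient(y, tt)
        else:
            v = np.zeros(1)  # single-frame play: no displacement evidence
        out[ybar.index.get_indexer(idx)] = v
    ybar["v_y"] = out
    return ybar.set_index(["play_id", "frame_index"])["v_y"]


class TrackingTable:
    """Validated long-format tracking table (thin pandas wrapper)."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        if validate:
            problems = _validate(df)
            if problems:
                raise TrackingSchemaError(problems)
        if "v_y" not in df.columns:
            v = _long_axis_velocity(df)
            key = pd.MultiIndex.from_frame(df[["play_id", "frame_index"]])
            df["v_y"] = v.reindex(key).to_numpy()
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def n_frames(self) -> int:
        return self.df.groupby(["play_id", "frame_index"]).ngroups

    @property
    def play_ids(self) -> np.ndarray:
        return self.df["play_id"].unique()

    def frames(self) -> Iterator[Frame]:
        """Iterate Frame objects in (play_id, frame_index) order."""
        for (pid, _fi), sub in self.df.groupby(["play_id", "frame_index"],
                                               sort=True):
            off = sub[sub.object_class == "offense"].sort_values("agent_id")
            dee = sub[sub.object_class == "defense"].sort_values("agent_id")
            ball = sub[sub.object_class == "ball"]
            yield Frame(play_id=pid,
                        t_to_shot=float(sub["t_to_shot"].iloc[0]),
                        offense=off[["x", "y"]].to_numpy(dtype=float),
                        defense=dee[["x", "y"]].to_numpy(dtype=float),
                        ball=ball[["x", "y"]].to_numpy(dtype=float)[0],
                        outcome=int(sub["outcome"].iloc[0]))

    def agent_positions(self, object_class: str, agent_id) -> pd.DataFrame:
        m = (self.df.object_class == object_class) & (self.df.agent_id == agent_id)
        return self.df[m]

    @classmethod
    def from_frames(cls, frames: Sequence[Frame],
                    agent_ids_offense=None, agent_ids_defense=None) -> "TrackingTable":
        """Assemble a table from Frame records (frame_index per play in order)."""
        if agent_ids_offense is None:
            agent_ids_offense = [f"o{i}" for i in range(5)]
        if agent_ids_defense is None:
            agent_ids_defense = [f"d{i}" for i in range(5)]
        rows = []
        counters: dict = {}
        for fr in frames:
            fi = counters.get(fr.play_id, 0)
            counters[fr.play_id] = fi + 1
            common = dict(play_id=fr.play_id, frame_index=fi,
                          t_to_shot=fr.t_to_shot, outcome=fr.outcome or 0)
            for aid, (x, y) in zip(agent_ids_offense, fr.offense):
                rows.append(dict(common, object_class="offense", agent_id=aid,
                                 x=x, y=y))
            for aid, (x, y) in zip(agent_ids_defense, fr.defense):
                rows.append(dict(common, object_class="defense", agent_id=aid,
                                 x=x, y=y))
            rows.append(dict(common, object_class="ball", agent_id=BALL_ID,
                             x=fr.ball[0], y=fr.ball[1]))
        return cls(pd.DataFrame(rows, columns=COLUMNS))


def read_tracking(path, dialect: str = "csv") -> TrackingTable:
    """Read and validate a tracking table (``csv`` or ``parquet``)."""
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return TrackingTable(df[COLUMNS] if set(COLUMNS) <= set(df.columns) else df)


def write_tracking(table: TrackingTable, path, dialect: str = "csv") -> None:
    df = table.df[COLUMNS]
    if dialect == "csv":
        df.to_csv(path, index=False)
    elif dialect == "parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# frame filters (pure: return new tables, closed threshold boundaries)

def _frame_mask(table: TrackingTable, keep: pd.Series) -> TrackingTable:
    key = pd.MultiIndex.from_frame(table.df[["play_id", "frame_index"]])
    out = TrackingTable.__new__(TrackingTable)
    out.df = table.df[keep.reindex(key).to_numpy()].copy()
    return out


def filter_pre_shot(table: TrackingTable, window: float = 3.0) -> TrackingTable:
    """Keep frames with 0 <= t_to_shot <= window seconds (closed boundary)."""
    t = table.df.groupby(["play_id", "frame_index"])["t_to_shot"].first()
    return _frame_mask(table, (t >= 0) & (t <= window))


def filter_transition(table: TrackingTable, depth: float = 20.0,
                      vmax: float = 5.0) -> TrackingTable:
    """Drop transition frames: keep only frames where the 10-agent mean y is
    at least ``depth`` ft beyond the half-court line and the magnitude of the
    mean long-axis velocity is at most ``vmax`` ft/s."""
    players = table.df[table.df.object_class != "ball"]
    g = players.groupby(["play_id", "frame_index"])
    ybar = g["y"].mean()
    v = g["v_y"].first()
    return _frame_mask(table, (ybar >= depth) & (v.abs() <= vmax))


def ball_weights(table: TrackingTable, anchor, sigma: float = 2.0) -> pd.Series:
    """Per-frame Gaussian weight exp(-d^2 / (2 sigma^2)) by ball-to-anchor
    distance, indexed by (play_id, frame_index)."""
    ball = table.df[table.df.object_class == "ball"]
    d2 = ((ball["x"] - anchor[0]) ** 2 + (ball["y"] - anchor[1]) ** 2)
    w = np.exp(-d2 / (2.0 * sigma ** 2))
    w.index = pd.MultiIndex.from_frame(ball[["play_id", "frame_index"]])
    return w


def testing_restriction(table: TrackingTable, anchors: np.ndarray,
                        radius: float = 2.0) -> TrackingTable:
    """Keep frames whose ball lies within ``radius`` ft (closed) of some
    anchor."""
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 2)
    ball = table.df[table.df.object_class == "ball"]
    pos = ball[["x", "y"]].to_numpy(dtype=float)
    d = np.linalg.norm(pos[:, None, :] - anchors[None, :, :], axis=2).min(axis=1)
    keep = pd.Series(d <= radius,
                     index=pd.MultiIndex.from_frame(ball[["play_id", "frame_index"]]))
    return _frame_mask(table, keep)


def split_plays(table: TrackingTable, train_frac: float = 0.8,
                seed: int = 0) -> tuple[TrackingTable, TrackingTable]:
    """Seeded play-level train/test split (no play straddles the split)."""
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    plays = np.sort(np.asarray(table.play_ids, dtype=object))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(plays))
    n_train = int(np.ceil(train_frac * len(plays)))
    train_ids = set(plays[order[:n_train]])
    m = table.df["play_id"].isin(train_ids).to_numpy()
    tr = TrackingTable.__new__(TrackingTable)
    tr.df = table.df[m].copy()
    te = TrackingTable.__new__(TrackingTable)
    te.df = table.df[~m].copy()
    return tr, te


# ---------------------------------------------------------------------------
# ball anchor set

@dataclass(frozen=True)
class BallAnchorSet:
    """Target ball locations for conditioning: 36 inside the 3-point arc and
    53 outside (89 total), with per-anchor Gaussian weighting (sigma = 2 ft).

    The default set is two symmetric square lattices clipped to the half
    court, 5.5 ft spacing inside the arc and 4.9 ft outside (a single uniform
    lattice cannot produce the 36/53 split because the inside-arc region
    covers about half the half-court area).
    """

    points: np.ndarray       # (n, 2)
    inside_arc: np.ndarray   # (n,) bool
    sigma: float = 2.0

    @classmethod
    def default(cls, sigma: float = 2.0) -> "BallAnchorSet":
        def lattice(s, ox, oy):
            xs = -25.0 + ox + s * np.arange(100)
            xs = xs[(xs >= -24.5) & (xs <= 24.5)]
            ys = oy + s * np.arange(100)
            ys = ys[(ys >= 1.0) & (ys <= 49.0)]
            X, Y = np.meshgrid(xs, ys)
            return np.column_stack([X.ravel(), Y.ravel()])
        inner = lattice(5.5, 3.0, 2.25)
        inner = inner[inside_three_point_arc(inner[:, 0], inner[:, 1])]
        outer = lattice(4.9, 0.5, 0.25)
        outer = outer[~inside_three_point_arc(outer[:, 0], outer[:, 1])]
        pts = np.vstack([inner, outer])
        inside = np.concatenate([np.ones(len(inner), bool),
                                 np.zeros(len(outer), bool)])
        return cls(pts, inside, sigma)

    def __len__(self):
        return len(self.points)

    @property
    def n_inside(self) -> int:
        return int(self.inside_arc.sum())

    @property
    def n_outside(self) -> int:
        return int((~self.inside_arc).sum())

    def weight(self, ball_xy, index: int) -> float:
        d2 = float(np.sum((np.asarray(ball_xy, float) - self.points[index]) ** 2))
        return float(np.exp(-d2 / (2.0 * self.sigma ** 2)))

    def nearest(self, xy) -> int:
        d = np.linalg.norm(self.points - np.asarray(xy, float), axis=1)
        return int(np.argmin(d))

    def to_csv(self, path) -> None:
        pd.DataFrame({"x": self.points[:, 0], "y": self.points[:, 1],
                      "inside_arc": self.inside_arc}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sigma: float = 2.0) -> "BallAnchorSet":
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(dtype=float),
                   df["inside_arc"].to_numpy(dtype=bool), sigma)
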