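"""Session data model and tabular interchange formats.

A session directory holds:

- ``tracking.csv``  : t, x, y, hd_deg       (39 Hz resampled tracking)
- ``spikes.csv``    : cell_id, t            (spike timestamps, s)
- ``epochs.csv``    : label, start, end     (wake / rem / nrem intervals, s)
- ``arena.json``    : {width_cm, height_cm, cells: [ids]}
- ``waveforms.csv`` : cell_id, duration_ms, trough_to_peak_ms  (optional)

Conventions: angles are radians in [0, 2*pi) internally (0 = +x axis, CCW
positive); degrees only in files. Coordinates are continuous cm with the
origin at the South-West corner; walls are East (x = width), North
(y = height), West (x = 0), South (y = 0).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .celltype import WaveformFeatures
from .circular import wrap_angle

logger = logging.getLogger("hdspace")

WALL_ORDER = ("east", "north", "west", "south")
EPOCH_LABELS = ("wake", "rem", "nrem")

#: default movement threshold, cm/s
SPEED_THRESHOLD = 2.5


class SessionFormatError(ValueError):
    """A required file is missing or malformed."""


class SessionValidationError(ValueError):
    """Data violates a session invariant (e.g. out-of-bounds positions)."""


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular walled arena. Default is the 53 x 46 cm recording box."""

    width: float = 53.0
    height: float = 46.0
    wall_labels: tuple = WALL_ORDER

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise ValueError("arena dimensions must be positive")
        if len(self.wall_labels) != 4:
            raise ValueError("exactly four walls required")

    def wall_distances(self, x, y):
        """Distances to (east, north, west, south) walls, shape (4, n)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.stack([self.width - x, self.height - y, x, y])

    def nearest_wall(self, x, y):
        """(wall index, distance) of the nearest wall per point.

        Ties at exact corners break toward the smaller index (E < N < W < S).
        """
        d = self.wall_distances(x, y)
        idx = np.argmin(d, axis=0)
        return idx, np.take_along_axis(d, idx[None], axis=0)[0]

    @property
    def wall_bearings(self):
        """Bearing from a point toward the perpendicular foot on each wall."""
        return np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])

    @property
    def center(self):
        return self.width / 2.0, self.height / 2.0


@dataclass
class Trajectory:
    """Array-backed tracking samples: time (s), position (cm), head direction.

    Rows play the role of individual trajectory samples; ``t`` is strictly
    increasing and ``hd`` is wrapped to [0, 2*pi).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd = wrap_angle(np.asarray(self.hd, dtype=float))
        n = self.t.size
        if not (self.x.size == self.y.size == self.hd.size == n):
            raise SessionValidationError("trajectory arrays differ in length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise SessionValidationError("trajectory times must be strictly increasing")

    @property
    def n(self):
        return self.t.size

    @property
    def duration(self):
        return float(self.t[-1] - self.t[0]) if self.n > 1 else 0.0

    def frame_dt(self):
        """Per-frame durations (s); the last frame repeats the previous dt.

        Durations are capped at twice the median so that gaps (e.g. between
        epoch intervals after slicing) do not inflate the occupancy of the
        frame preceding the gap.
        """
        if self.n < 2:
            return np.zeros(self.n)
        d = np.diff(self.t)
        d = np.minimum(d, 2.0 * np.median(d))
        return np.append(d, d[-1])

    def frame_index(self, times):
        """Index of the frame whose [t_i, t_{i+1}) interval contains each time.

        Uses O(1) arithmetic when the sampling grid is regular.
        """
        times = np.asarray(times, dtype=float)
        if self.n == 0:
            raise ValueError("empty trajectory")
        if self.n > 1:
            dt = (self.t[-1] - self.t[0]) / (self.n - 1)
            if np.max(np.abs(np.diff(self.t) - dt)) < 1e-9:
                idx = np.floor((times - self.t[0]) / dt).astype(np.int64)
                return np.clip(idx, 0, self.n - 1)
        idx = np.searchsorted(self.t, times, side="right") - 1
        return np.clip(idx, 0, self.n - 1)

    def slice(self, sel):
        return Trajectory(self.t[sel], self.x[sel], self.y[sel], self.hd[sel])


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (s) for one cell."""

    cell_id: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, dtype=float))

    @property
    def n(self):
        return self.times.size


@dataclass
class EpochSet:
    """Non-overlapping labeled intervals, e.g. wake / rem / nrem."""

    label: str
    intervals: np.ndarray  # (n, 2) start < end

    def __post_init__(self):
        self.intervals = np.atleast_2d(np.asarray(self.intervals, dtype=float))
        if self.intervals.size == 0:
            self.intervals = np.empty((0, 2))
        if self.intervals.shape[1] != 2:
            raise SessionValidationError("epoch intervals must be (n, 2)")
        if np.any(self.intervals[:, 0] >= self.intervals[:, 1]):
            raise SessionValidationError(f"epoch '{self.label}': start >= end")
        order = np.argsort(self.intervals[:, 0])
        self.intervals = self.intervals[order]
        if np.any(self.intervals[1:, 0] < self.intervals[:-1, 1]):
            raise SessionValidationError(f"epoch '{self.label}': overlapping intervals")

    @property
    def total_duration(self):
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, times):
        """Boolean mask: which times fall inside any interval."""
        times = np.asarray(times, dtype=float)
        out = np.zeros(times.shape, dtype=bool)
        for s, e in self.intervals:
            out |= (times >= s) & (times < e)
        return out


@dataclass
class Session:
    """One recording: arena, trajectory, spike trains, state epochs."""

    arena: ArenaSpec
    trajectory: Trajectory
    spikes: list = field(default_factory=list)
    epochs: list = field(default_factory=list)
    waveform_features: dict = field(default_factory=dict)

    @property
    def cell_ids(self):
        return [s.cell_id for s in self.spikes]

    def spike_train(self, cell_id) -> SpikeTrain:
        for s in self.spikes:
            if s.cell_id == cell_id:
                return s
        raise KeyError(cell_id)

    def epoch(self, label):
        for e in self.epochs:
            if e.label == label:
                return e
        return None

    def validate(self):
        """Raise SessionValidationError on any invariant violation."""
        traj = self.trajectory
        if traj.n == 0:
            raise SessionValidationError("empty trajectory")
        eps = 1e-9
        oob = np.nonzero(
            (traj.x < -eps)
            | (traj.x > self.arena.width + eps)
            | (traj.y < -eps)
            | (traj.y > self.arena.height + eps)
        )[0]
        if oob.size:
            raise SessionValidationError(
                f"positions outside arena at rows {oob[:10].tolist()}"
                + ("..." if oob.size > 10 else "")
            )
        dt = traj.frame_dt()
        frame = float(dt.max()) if dt.size else 0.0
        lo, hi = traj.t[0] - frame, traj.t[-1] + frame
        for train in self.spikes:
            if train.n and (train.times[0] < lo or train.times[-1] > hi):
                raise SessionValidationError(
                    f"cell {train.cell_id}: spikes outside trajectory span"
                )
        for ep in self.epochs:
            if ep.label not in EPOCH_LABELS:
                raise SessionValidationError(f"unknown epoch label '{ep.label}'")
            if ep.intervals.size and (
                ep.intervals.min() < lo or ep.intervals.max() > hi
            ):
                raise SessionValidationError(
                    f"epoch '{ep.label}' outside trajectory span"
                )
        return self


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionFormatError(f"missing required file: {path}")
    return path


def read_session(path) -> Session:
    """Read and validate a session directory (see module docstring)."""
    path = Path(path)
    if not path.is_dir():
        raise SessionFormatError(f"not a directory: {path}")
    with open(_require(path / "arena.json")) as fh:
        meta = json.load(fh)
    try:
        arena = ArenaSpec(width=float(meta["width_cm"]), height=float(meta["height_cm"]))
        registry = [str(c) for c in meta.get("cells", [])]
    except (KeyError, TypeError) as exc:
        raise SessionFormatError(f"malformed arena.json: {exc}") from exc

    track = pd.read_csv(_require(path / "tracking.csv"))
    for col in ("t", "x", "y", "hd_deg"):
        if col not in track.columns:
            raise SessionFormatError(f"tracking.csv missing column '{col}'")
    track = track.sort_values("t", kind="stable").reset_index(drop=True)
    traj = Trajectory(
        t=track["t"].to_numpy(),
        x=track["x"].to_numpy(),
        y=track["y"].to_numpy(),
        hd=np.deg2rad(track["hd_deg"].to_numpy()),
    )

    sp = pd.read_csv(_require(path / "spikes.csv"))
    for col in ("cell_id", "t"):
        if col not in sp.columns:
            raise SessionFormatError(f"spikes.csv missing column '{col}'")
    by_cell = {str(cid): g["t"].to_numpy() for cid, g in sp.groupby("cell_id")}
    order = registry + sorted(set(by_cell) - set(registry))
    spikes = [SpikeTrain(cid, by_cell.get(cid, np.empty(0))) for cid in order]

    ep = pd.read_csv(_require(path / "epochs.csv"))
    for col in ("label", "start", "end"):
        if col not in ep.columns:
            raise SessionFormatError(f"epochs.csv missing column '{col}'")
    epochs = [
        EpochSet(str(label), g[["start", "end"]].to_numpy())
        for label, g in ep.groupby("label", sort=False)
    ]

    waveforms = {}
    wf_path = path / "waveforms.csv"
    if wf_path.exists():
        wf = pd.read_csv(wf_path)
        for _, row in wf.iterrows():
            waveforms[str(row["cell_id"])] = WaveformFeatures(
                duration_ms=float(row["duration_ms"]),
                trough_to_peak_ms=float(row["trough_to_peak_ms"]),
            )

    session = Session(arena, traj, spikes, epochs, waveforms)
    session.validate()
    return session


def write_session(session: Session, path) -> None:
    """Write a session directory; read_session round-trips to <=1e-9."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    traj = session.trajectory
    pd.DataFrame(
        {"t": traj.t, "x": traj.x, "y": traj.y, "hd_deg": np.rad2deg(traj.hd)}
    ).to_csv(path / "tracking.csv", index=False)

    rows = [
        pd.DataFrame({"cell_id": train.cell_id, "t": train.times})
        for train in session.spikes
        if train.n
    ]
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame({"cell_id": pd.Series(dtype=str), "t": pd.Series(dtype=float)})
    )
    spikes.to_csv(path / "spikes.csv", index=False)

    ep_rows = []
    for ep in session.epochs:
        for s, e in ep.intervals:
            ep_rows.append({"label": ep.label, "start": s, "end": e})
    pd.DataFrame(ep_rows, columns=["label", "start", "end"]).to_csv(
        path / "epochs.csv", index=False
    )

    with open(path / "arena.json", "w") as fh:
        json.dump(
            {
                "width_cm": session.arena.width,
                "height_cm": session.arena.height,
                "cells": session.cell_ids,
            },
            fh,
            indent=1,
        )

    if session.waveform_features:
        pd.DataFrame(
            [
                {
                    "cell_id": cid,
                    "duration_ms": wf.duration_ms,
                    "trough_to_peak_ms": wf.trough_to_peak_ms,
                }
                for cid, wf in session.waveform_features.items()
            ]
        ).to_csv(path / "waveforms.csv", index=False)


def epoch_view(session: Session, label: str):
    """Trajectory and spike trains restricted to one epoch's intervals.

    Used to run wake-only analyses on sessions that also contain sleep.
    """
    ep = session.epoch(label)
    if ep is None:
        raise KeyError(f"session has no '{label}' epoch")
    sel = ep.contains(session.trajectory.t)
    if not sel.any():
        raise SessionValidationError(f"epoch '{label}' covers no tracking samples")
    traj = session.trajectory.slice(sel)
    spikes = [
        SpikeTrain(s.cell_id, s.times[ep.contains(s.times)]) for s in session.spikes
    ]
    return traj, spikes


# ---------------------------------------------------------------------------
# movement filter
# ---------------------------------------------------------------------------

def _moving_average(v, window):
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def speed_filter(trajectory: Trajectory, threshold: float = SPEED_THRESHOLD,
                 smooth_window: int = 3) -> np.ndarray:
    """Boolean movement mask: instantaneous speed > threshold (cm/s).

    Positions are smoothed with a short moving average, then speed is taken
    by central differences (one-sided at the ends). All behavioral measures
    downstream are computed on masked (moving) samples only.
    """
    if trajectory.n < 2:
        raise ValueError("speed_filter needs at least 2 samples")
    xs = _moving_average(trajectory.x, smooth_window)
    ys = _moving_average(trajectory.y, smooth_window)
    vx = np.gradient(xs, trajectory.t)
    vy = np.gradient(ys, trajectory.t)
    return np.hypot(vx, vy) > threshold
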