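"""Synthetic sessions with known ground truth.

Every downstream stage of the pipeline is verified by parameter recovery on
data from this module: a biased random-walk trajectory in a walled arena,
parametric cell models (von Mises head-direction tuning, optionally gated by
wall proximity or by the egocentric bearing of the nearest wall, plus place
and homogeneous cells), inhomogeneous Poisson spiking, and "sleep" driven by
a latent drifting heading with spatial inputs disconnected.

The trajectory generator couples head direction to movement heading (plus
von Mises jitter) and steers the walk parallel to the nearest wall when
close to it. That coupling is what produces the position-dependent heading
bias — and hence the spurious spatial information of pure HD cells — that
the analysis modules are designed to measure and correct.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .celltype import WaveformFeatures
from .circular import TWO_PI, wrap_angle, wrap_pi
from .io_core import ArenaSpec, EpochSet, Session, SpikeTrain, Trajectory

#: wall-interaction zone (cm); matches the analyzer's wall distance so the
#: generator and the GLM regressors describe the same geometry
WALL_ZONE_CM = 15.0

#: egocentric acceptance half-window (deg), matching the analyzer
EGO_HALF_WINDOW_DEG = 60.0

CELL_KINDS = ("pure_hd", "hd_border", "hd_egocentric", "place", "homogeneous")


@dataclass(frozen=True)
class TrajectoryParams:
    """Biased-ambulation random walk parameters.

    Defaults emulate a mouse foraging in an open box: ~8 cm/s typical speed,
    heading decorrelation within a second, and a thigmotactic wall-following
    tendency (wall_bias) strong enough that most time is spent in the 15 cm
    wall band, as rodents do in open arenas.
    """

    duration: float = 600.0
    frame_rate: float = 39.0
    mean_speed: float = 8.0
    speed_sd: float = 4.0
    turn_sd: float = 0.25
    wall_bias: float = 2.0
    hd_jitter_kappa: float = 20.0
    seed: int = 0

    def __post_init__(self):
        vals = [self.duration, self.frame_rate, self.mean_speed, self.speed_sd,
                self.turn_sd, self.wall_bias, self.hd_jitter_kappa]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite trajectory parameter")
        if self.duration < 0 or self.frame_rate <= 0 or self.wall_bias < 0:
            raise ValueError("invalid trajectory parameter")


@dataclass(frozen=True)
class CellModel:
    """Parametric firing-rate model.

    kind:
      - pure_hd:       baseline + (peak-baseline) * exp(kappa*(cos(hd-pref)-1))
      - hd_border:     pure_hd rate x gain of nearest wall when within
                       wall_distance of it (x1 otherwise)
      - hd_egocentric: pure_hd rate x left/right gain when the nearest wall
                       (<= wall_distance) lies within +-60 deg of the left /
                       right body axis
      - place:         baseline + (peak-baseline) * Gaussian bump
      - homogeneous:   baseline
    """

    kind: str = "pure_hd"
    peak_rate: float = 10.0
    baseline_rate: float = 1.0
    preferred_direction: float = 0.0
    kappa: float = 4.0
    gain_per_wall: tuple = (1.0, 1.0, 1.0, 1.0)  # east, north, west, south
    side_gain: tuple = (1.5, 0.5)  # (left_gain, right_gain)
    place_center: Optional[tuple] = None
    place_sigma: float = 5.0
    wall_distance: float = WALL_ZONE_CM

    def __post_init__(self):
        if self.kind not in CELL_KINDS:
            raise ValueError(f"unknown cell kind '{self.kind}'")
        if self.peak_rate < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.kind in ("pure_hd", "hd_border", "hd_egocentric") and self.kappa <= 0:
            raise ValueError("kappa must be positive for HD kinds")
        if any(g < 0 for g in self.gain_per_wall) or any(g < 0 for g in self.side_gain):
            raise ValueError("gains must be non-negative")

    def as_pure_hd(self) -> "CellModel":
        """The HD-only reduction of this model (gains stripped)."""
        return replace(self, kind="pure_hd")


@dataclass(frozen=True)
class SleepParams:
    """Latent-heading sleep: a wrapped Gaussian random walk drives HD cells.

    drift_sd is in rad/sqrt(s); the default mixes the latent heading over the
    full circle within a couple of minutes, giving good angular coverage in a
    10 min sleep epoch while retaining second-scale autocorrelation.
    """

    duration: float = 600.0
    frame_rate: float = 39.0
    drift_sd: float = 0.5
    spatial_decouple: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.drift_sd <= 0 or self.frame_rate <= 0:
            raise ValueError("invalid sleep parameter")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(arena: ArenaSpec, params: TrajectoryParams) -> Trajectory:
    """Simulate a biased random walk with reflective walls.

    Head direction equals the instantaneous movement heading plus small von
    Mises jitter. When within WALL_ZONE_CM of the nearest wall and
    wall_bias > 0, the heading relaxes toward the closer of the two wall
    tangent directions, producing wall-following.
    """
    n = int(round(params.duration * params.frame_rate))
    dt = 1.0 / params.frame_rate
    if n == 0:
        return Trajectory(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    rng = np.random.default_rng(params.seed)
    margin = 1.0
    speeds = np.clip(rng.normal(params.mean_speed, params.speed_sd, n), 0.0, None)
    turns = rng.normal(0.0, params.turn_sd, n)
    jitter = (
        rng.vonmises(0.0, params.hd_jitter_kappa, n)
        if params.hd_jitter_kappa > 0
        else np.zeros(n)
    )
    # steering gain: at the wall (d=0) with wall_bias=1 the heading relaxes
    # toward the tangent with rate 4/s
    steer = 4.0 * params.wall_bias * dt

    x = np.empty(n)
    y = np.empty(n)
    phi_arr = np.empty(n)
    cx, cy = arena.center
    px, py = cx, cy
    phi = rng.uniform(0.0, TWO_PI)
    w, h = arena.width, arena.height
    for i in range(n):
        d4 = (w - px, h - py, px, py)
        widx = int(np.argmin(d4))
        d = d4[widx]
        if params.wall_bias > 0 and d < WALL_ZONE_CM:
            # tangents of wall widx: perpendicular to its normal bearing
            normal = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)[widx]
            t1 = normal + np.pi / 2
            d1 = wrap_pi(t1 - phi)
            d2 = wrap_pi(t1 + np.pi - phi)
            delta = d1 if abs(d1) <= abs(d2) else d2
            phi += steer * (1.0 - d / WALL_ZONE_CM) * delta
        phi += turns[i]
        x[i], y[i] = px, py
        phi_arr[i] = phi
        px += speeds[i] * dt * np.cos(phi)
        py += speeds[i] * dt * np.sin(phi)
        if px < margin:
            px = 2 * margin - px
            phi = np.pi - phi
        elif px > w - margin:
            px = 2 * (w - margin) - px
            phi = np.pi - phi
        if py < margin:
            py = 2 * margin - py
            phi = -phi
        elif py > h - margin:
            py = 2 * (h - margin) - py
            phi = -phi
        px = min(max(px, margin), w - margin)
        py = min(max(py, margin), h - margin)
    hd = wrap_angle(phi_arr + jitter)
    t = np.arange(n) * dt
    return Trajectory(t, x, y, hd)


# ---------------------------------------------------------------------------
# firing-rate models
# ---------------------------------------------------------------------------

def _von_mises_shape(hd, preferred, kappa):
    """von Mises bump normalized to max 1 (exactly 1 at hd = preferred)."""
    return np.exp(kappa * (np.cos(hd - preferred) - 1.0))


def cell_rate(model: CellModel, trajectory: Trajectory, arena: ArenaSpec) -> np.ndarray:
    """Instantaneous firing rate (Hz) of the model at each trajectory sample."""
    hd, x, y = trajectory.hd, trajectory.x, trajectory.y
    if model.kind == "homogeneous":
        return np.full(hd.shape, float(model.baseline_rate))
    if model.kind == "place":
        cx, cy = model.place_center if model.place_center is not None else arena.center
        bump = np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * model.place_sigma**2)
        )
        return model.baseline_rate + (model.peak_rate - model.baseline_rate) * bump

    rate = model.baseline_rate + (model.peak_rate - model.baseline_rate) * \
        _von_mises_shape(hd, model.preferred_direction, model.kappa)
    if model.kind == "pure_hd":
        return rate

    widx, d = arena.nearest_wall(x, y)
    near = d <= model.wall_distance
    if model.kind == "hd_border":
        gains = np.asarray(model.gain_per_wall, dtype=float)[widx]
        return rate * np.where(near, gains, 1.0)

    # hd_egocentric: gate on the signed angle from hd to the nearest-wall
    # bearing; left body axis = hd + 90 deg, right = hd - 90 deg
    bearing = arena.wall_bearings[widx]
    phi = wrap_pi(bearing - hd)
    half = np.deg2rad(EGO_HALF_WINDOW_DEG)
    left = near & (np.abs(wrap_pi(phi - np.pi / 2)) <= half)
    right = near & (np.abs(wrap_pi(phi + np.pi / 2)) <= half)
    gain = np.where(left, model.side_gain[0], np.where(right, model.side_gain[1], 1.0))
    return rate * gain


def generate_spikes(model: CellModel, trajectory: Trajectory, arena: ArenaSpec,
                    seed: int = 0, cell_id: str = "cell") -> SpikeTrain:
    """Inhomogeneous Poisson spikes: per-frame count ~ Poisson(rate * dt),
    spike times uniformly jittered within the frame."""
    if trajectory.n == 0:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(seed)
    rates = cell_rate(model, trajectory, arena)
    if np.any(rates < 0):
        raise ValueError("negative firing rate")
    dtf = trajectory.frame_dt()
    counts = rng.poisson(rates * dtf)
    total = int(counts.sum())
    if total == 0:
        return SpikeTrain(cell_id, np.empty(0))
    starts = np.repeat(trajectory.t, counts)
    widths = np.repeat(dtf, counts)
    times = starts + rng.random(total) * widths
    return SpikeTrain(cell_id, times)


# ---------------------------------------------------------------------------
# sleep
# ---------------------------------------------------------------------------

def sleep_model(model: CellModel, spatial_decouple: bool = True) -> CellModel:
    """The model that applies during sleep.

    With spatial inputs decoupled, HD kinds reduce to their pure-HD form on
    the latent heading, and place cells fall back to baseline firing.
    """
    if model.kind in ("pure_hd", "hd_border", "hd_egocentric"):
        return model.as_pure_hd() if spatial_decouple else model
    if model.kind == "place" and spatial_decouple:
        return replace(model, kind="homogeneous")
    return model


def simulate_sleep(models, params: SleepParams, arena: ArenaSpec = None,
                   cell_ids=None):
    """Simulate a sleep epoch driven by a latent drifting heading.

    Returns (Trajectory, [SpikeTrain]): a virtual trajectory pinned at the
    arena center whose ``hd`` is the latent heading (wrapped Gaussian random
    walk), and one spike train per model, generated from each model's sleep
    reduction (see ``sleep_model``).
    """
    if len(models) == 0:
        raise ValueError("at least one cell model required")
    arena = arena if arena is not None else ArenaSpec()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    dt = 1.0 / params.frame_rate
    theta0 = rng.uniform(0.0, TWO_PI)
    steps = rng.normal(0.0, params.drift_sd * np.sqrt(dt), n)
    theta = wrap_angle(theta0 + np.concatenate([[0.0], np.cumsum(steps[:-1])]))
    cx, cy = arena.center
    traj = Trajectory(np.arange(n) * dt, np.full(n, cx), np.full(n, cy), theta)
    if cell_ids is None:
        cell_ids = [f"cell{i:03d}" for i in range(len(models))]
    seeds = np.random.SeedSequence(params.seed).spawn(len(models))
    trains = []
    for model, cid, ss in zip(models, cell_ids, seeds):
        reduced = sleep_model(model, params.spatial_decouple)
        trains.append(
            generate_spikes(reduced, traj, arena,
                            seed=ss.generate_state(1)[0] % (2**31), cell_id=cid)
        )
    return traj, trains


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------

def _shift_trajectory(traj: Trajectory, offset: float) -> Trajectory:
    return Trajectory(traj.t + offset, traj.x, traj.y, traj.hd)


def simulate_session(models, arena: ArenaSpec = None,
                     traj_params: TrajectoryParams = None,
                     sleep_params: SleepParams = None,
                     seed: int = 0, waveforms: dict = None,
                     include_rem: bool = True) -> Session:
    """Build a full synthetic session: wake exploration plus, optionally, one
    non-REM and one REM sleep segment on independent latent headings.

    ``seed`` expands into independent streams for the trajectory, each cell's
    wake spikes, and each sleep segment.
    """
    arena = arena if arena is not None else ArenaSpec()
    traj_params = traj_params if traj_params is not None else TrajectoryParams()
    root = np.random.SeedSequence(seed)
    ss_traj, ss_cells, ss_nrem, ss_rem = root.spawn(4)

    wake_traj = simulate_trajectory(
        arena, replace(traj_params, seed=int(ss_traj.generate_state(1)[0] % (2**31)))
    )
    cell_ids = [f"cell{i:03d}" for i in range(len(models))]
    cell_seeds = ss_cells.spawn(len(models))
    spikes = [
        generate_spikes(m, wake_traj, arena,
                        seed=int(s.generate_state(1)[0] % (2**31)), cell_id=cid)
        for m, cid, s in zip(models, cell_ids, cell_seeds)
    ]
    dt = 1.0 / traj_params.frame_rate
    t_end = wake_traj.t[-1] + dt if wake_traj.n else 0.0
    epochs = [EpochSet("wake", np.array([[0.0, t_end]]))]
    traj_parts = [wake_traj]

    if sleep_params is not None:
        labels = ["nrem"] + (["rem"] if include_rem else [])
        seeds = [ss_nrem, ss_rem]
        for label, ss in zip(labels, seeds):
            sp = replace(sleep_params, seed=int(ss.generate_state(1)[0] % (2**31)))
            straj, strains = simulate_sleep(models, sp, arena, cell_ids=cell_ids)
            straj = _shift_trajectory(straj, t_end)
            for train, extra in zip(spikes, strains):
                train.times = np.sort(np.concatenate([train.times, extra.times + t_end]))
            seg_end = straj.t[-1] + dt
            epochs.append(EpochSet(label, np.array([[t_end, seg_end]])))
            traj_parts.append(straj)
            t_end = seg_end

    full = Trajectory(
        np.concatenate([p.t for p in traj_parts]),
        np.concatenate([p.x for p in traj_parts]),
        np.concatenate([p.y for p in traj_parts]),
        np.concatenate([p.hd for p in traj_parts]),
    )
    wf = {}
    if waveforms:
        for cid, feats in waveforms.items():
            wf[cid] = feats if isinstance(feats, WaveformFeatures) else \
                WaveformFeatures(*feats)
    return Session(arena, full, spikes, epochs, wf).validate()
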