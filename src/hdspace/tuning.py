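"""Head-direction tuning curves, HD-cell classification, and spatial rate maps.

HD tuning is estimated by counting spikes per 6 deg head-direction bin and
dividing by the occupancy (seconds) of that bin, over speed-masked samples.
A cell is classified as a head-direction cell when three criteria hold
jointly: a circular-shift shuffle test on the tuning-curve resultant length
(1000 shuffles, p <= 0.001), split-half tuning stability (Pearson r > 0.75),
and a von Mises concentration of the tuning curve above 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import pearsonr

from .circular import TWO_PI, kappa_from_resultant, resultant
from .io_core import ArenaSpec, SpikeTrain, Trajectory

logger = logging.getLogger("hdspace")

#: number of head-direction bins (6 deg each)
HD_BIN_COUNT = 60
HD_BIN_WIDTH = TWO_PI / HD_BIN_COUNT

#: guard (s) for circular spike-train shifts in the shuffle test
SHUFFLE_GUARD_S = 20.0


def hd_bin_index(hd):
    """Map wrapped angles to bin indices 0..59."""
    idx = np.floor(np.mod(hd, TWO_PI) / HD_BIN_WIDTH).astype(np.int64)
    return np.clip(idx, 0, HD_BIN_COUNT - 1)


def hd_bin_centers():
    return (np.arange(HD_BIN_COUNT) + 0.5) * HD_BIN_WIDTH


@dataclass
class HDTuningCurve:
    """Occupancy-normalized firing rate per 6 deg HD bin.

    ``rate`` is nan in bins with zero occupancy (flagged, excluded from all
    downstream sums); ``mean_rate`` is total spikes / total occupancy.
    """

    bin_edges: np.ndarray  # (61,)
    rate: np.ndarray  # (60,) Hz, nan where unvisited
    occupancy_s: np.ndarray  # (60,)
    mean_rate: float

    @property
    def bin_centers(self):
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def visited(self):
        return self.occupancy_s > 0

    def rate_at(self, hd, fill=0.0):
        """Tuning-curve rate looked up at arbitrary headings (nan -> fill)."""
        r = self.rate[hd_bin_index(hd)]
        return np.where(np.isfinite(r), r, fill)


@dataclass
class RateMap:
    """Occupancy-normalized firing rate per spatial bin.

    Spike-count and occupancy maps are each smoothed with an isotropic
    Gaussian (sigma in cm) before division; unvisited bins are nan.
    ``occupancy_p`` sums to 1 over visited bins.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    rate: np.ndarray  # (nx, ny) Hz
    occupancy_p: np.ndarray  # (nx, ny), sums to 1 over visited bins
    bin_size: float
    smoothing_sigma: float
    mean_rate: float
    visited: np.ndarray  # (nx, ny) bool


@dataclass
class HDClassification:
    is_hd: bool
    shuffle_p: float
    split_half_r: float
    concentration: float
    resultant_length: float
    preferred_direction: float


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

def _spike_frames(spikes: SpikeTrain, trajectory: Trajectory):
    return trajectory.frame_index(spikes.times)


def spikes_to_frame_counts(spikes: SpikeTrain, trajectory: Trajectory):
    """Per-frame spike counts (frame = tracking sample interval)."""
    return np.bincount(_spike_frames(spikes, trajectory), minlength=trajectory.n)


def compute_hd_tuning(spikes: SpikeTrain, trajectory: Trajectory,
                      mask: Optional[np.ndarray] = None) -> HDTuningCurve:
    """Spike count per 6 deg HD bin divided by occupancy (s) of that bin."""
    if trajectory.n == 0:
        raise ValueError("empty trajectory")
    mask = np.ones(trajectory.n, dtype=bool) if mask is None else np.asarray(mask)
    dtf = trajectory.frame_dt()
    bins = hd_bin_index(trajectory.hd)
    occupancy = np.bincount(bins[mask], weights=dtf[mask], minlength=HD_BIN_COUNT)
    if occupancy.sum() <= 0:
        raise ValueError("no occupancy under the given mask")
    frames = _spike_frames(spikes, trajectory)
    frames = frames[mask[frames]]
    counts = np.bincount(bins[frames], minlength=HD_BIN_COUNT).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
    mean_rate = float(counts.sum() / occupancy.sum())
    edges = np.arange(HD_BIN_COUNT + 1) * HD_BIN_WIDTH
    return HDTuningCurve(edges, rate, occupancy, mean_rate)


def resultant_vector(curve: HDTuningCurve):
    """Rate-weighted circular resultant of the tuning curve.

    Returns (length in [0, 1], direction in rad); all-zero curves return
    (0, nan).
    """
    ok = curve.visited & np.isfinite(curve.rate)
    if not ok.any():
        raise ValueError("tuning curve has no visited bins")
    if np.nansum(curve.rate[ok]) <= 0:
        return 0.0, np.nan
    return resultant(curve.bin_centers[ok], curve.rate[ok])


def concentration(curve: HDTuningCurve, cap: float = 1e6) -> float:
    """Von Mises concentration of the tuning curve via A(kappa) inversion of
    the rate-weighted resultant length."""
    r, _ = resultant_vector(curve)
    if not np.isfinite(r):
        raise ValueError("concentration undefined for all-zero curve")
    return kappa_from_resultant(r, cap=cap)


# ---------------------------------------------------------------------------
# shuffle test
# ---------------------------------------------------------------------------

def _resultant_lengths_from_counts(counts, occupancy, cosb, sinb):
    """Resultant length per row of a (n, 60) spike-count matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, 0.0)
    total = rate.sum(axis=1)
    c = rate @ cosb
    s = rate @ sinb
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.hypot(c, s) / total
    return np.where(total > 0, out, 0.0)


def shuffle_test(spikes: SpikeTrain, trajectory: Trajectory,
                 mask: Optional[np.ndarray] = None, n_shuffles: int = 1000,
                 seed: int = 0, guard_s: float = SHUFFLE_GUARD_S) -> float:
    """Circular-shift shuffle test of HD tuning.

    Each shuffle shifts all spike times by a uniform offset in
    [guard, T - guard] (circularly, preserving ISI structure) and recomputes
    the tuning-curve resultant length; p = (1 + #{R_shuffled >= R_obs}) /
    (n_shuffles + 1).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    if trajectory.n < 2:
        raise ValueError("trajectory too short")
    t0 = trajectory.t[0]
    span = trajectory.duration + float(trajectory.frame_dt()[-1])
    if span < 2 * guard_s:
        raise ValueError("session shorter than twice the shuffle guard")
    mask = np.ones(trajectory.n, dtype=bool) if mask is None else np.asarray(mask)
    dtf = trajectory.frame_dt()
    bins = hd_bin_index(trajectory.hd)
    occupancy = np.bincount(bins[mask], weights=dtf[mask], minlength=HD_BIN_COUNT)
    centers = hd_bin_centers()
    cosb, sinb = np.cos(centers), np.sin(centers)

    def counts_for(times_2d):
        idx = trajectory.frame_index(times_2d.ravel()).reshape(times_2d.shape)
        w = mask[idx].astype(float)
        b = bins[idx]
        rows = np.broadcast_to(
            np.arange(times_2d.shape[0])[:, None], times_2d.shape
        )
        flat = rows.ravel() * HD_BIN_COUNT + b.ravel()
        return np.bincount(
            flat, weights=w.ravel(), minlength=times_2d.shape[0] * HD_BIN_COUNT
        ).reshape(times_2d.shape[0], HD_BIN_COUNT)

    obs_counts = counts_for(spikes.times[None, :])
    r_obs = _resultant_lengths_from_counts(obs_counts, occupancy, cosb, sinb)[0]

    rng = np.random.default_rng(seed)
    offsets = rng.uniform(guard_s, span - guard_s, n_shuffles)
    shifted = np.mod(spikes.times[None, :] - t0 + offsets[:, None], span) + t0
    r_sh = _resultant_lengths_from_counts(
        counts_for(shifted), occupancy, cosb, sinb
    )
    return float((1 + np.sum(r_sh >= r_obs)) / (n_shuffles + 1))


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def split_half_stability(spikes: SpikeTrain, trajectory: Trajectory,
                         mask: Optional[np.ndarray] = None,
                         min_common_bins: int = 10) -> float:
    """Pearson correlation between first- and second-half tuning curves over
    commonly visited bins; nan (criterion fails) if fewer than
    ``min_common_bins`` bins are shared."""
    mask = np.ones(trajectory.n, dtype=bool) if mask is None else np.asarray(mask)
    mid_t = (trajectory.t[0] + trajectory.t[-1]) / 2.0
    first = trajectory.t <= mid_t
    curves = []
    for half in (first, ~first):
        sel = np.nonzero(half)[0]
        sub = trajectory.slice(sel)
        in_half = (spikes.times >= sub.t[0]) & (spikes.times <= sub.t[-1])
        curves.append(
            compute_hd_tuning(SpikeTrain(spikes.cell_id, spikes.times[in_half]),
                              sub, mask[sel])
        )
    a, b = curves
    common = a.visited & b.visited & np.isfinite(a.rate) & np.isfinite(b.rate)
    if common.sum() < min_common_bins:
        logger.warning("split_half_stability: only %d common bins", common.sum())
        return np.nan
    if np.std(a.rate[common]) == 0 or np.std(b.rate[common]) == 0:
        return np.nan
    return float(pearsonr(a.rate[common], b.rate[common])[0])


def classify_hd_cell(spikes: SpikeTrain, trajectory: Trajectory,
                     mask: Optional[np.ndarray] = None, seed: int = 0,
                     n_shuffles: int = 1000, p_threshold: float = 0.001,
                     r_threshold: float = 0.75,
                     kappa_threshold: float = 1.0) -> HDClassification:
    """Conjunction of shuffle significance, split-half stability and
    tuning-curve concentration."""
    curve = compute_hd_tuning(spikes, trajectory, mask)
    r_len, pref = resultant_vector(curve)
    kappa = kappa_from_resultant(r_len, cap=1e6)
    p = shuffle_test(spikes, trajectory, mask, n_shuffles=n_shuffles, seed=seed)
    stab = split_half_stability(spikes, trajectory, mask)
    is_hd = bool(
        (p <= p_threshold)
        and np.isfinite(stab)
        and (stab > r_threshold)
        and (kappa > kappa_threshold)
    )
    return HDClassification(is_hd, p, stab, kappa, r_len, pref)


# ---------------------------------------------------------------------------
# rate maps
# ---------------------------------------------------------------------------

def _spatial_bins(arena: ArenaSpec, bin_size: float):
    nx = int(np.ceil(arena.width / bin_size))
    ny = int(np.ceil(arena.height / bin_size))
    return (np.arange(nx + 1) * bin_size, np.arange(ny + 1) * bin_size)


def spatial_bin_index(trajectory: Trajectory, arena: ArenaSpec, bin_size: float):
    """Flattened spatial-bin index per frame (half-open [lo, hi) bins)."""
    x_edges, y_edges = _spatial_bins(arena, bin_size)
    nx, ny = x_edges.size - 1, y_edges.size - 1
    ix = np.clip((trajectory.x // bin_size).astype(np.int64), 0, nx - 1)
    iy = np.clip((trajectory.y // bin_size).astype(np.int64), 0, ny - 1)
    return ix * ny + iy, (nx, ny)


def rate_map_from_frame_counts(frame_counts, trajectory: Trajectory,
                               arena: ArenaSpec, mask=None,
                               bin_size: float = 0.5,
                               sigma: float = 2.5) -> RateMap:
    """Rate map given per-frame spike counts (shared by observed and
    surrogate estimators, so the bias correction is measured on the
    identical estimator)."""
    mask = np.ones(trajectory.n, dtype=bool) if mask is None else np.asarray(mask)
    if not mask.any():
        raise ValueError("empty mask")
    flat, (nx, ny) = spatial_bin_index(trajectory, arena, bin_size)
    dtf = trajectory.frame_dt()
    occ = np.bincount(flat[mask], weights=dtf[mask], minlength=nx * ny)
    cnt = np.bincount(flat[mask], weights=np.asarray(frame_counts, float)[mask],
                      minlength=nx * ny)
    occ = occ.reshape(nx, ny)
    cnt = cnt.reshape(nx, ny)
    visited = occ > 0
    if sigma > 0:
        sb = sigma / bin_size
        occ_s = gaussian_filter(occ, sb, mode="constant")
        cnt_s = gaussian_filter(cnt, sb, mode="constant")
    else:
        occ_s, cnt_s = occ, cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_s > 0, cnt_s / np.where(occ_s > 0, occ_s, 1.0), np.nan)
    rate = np.where(visited, rate, np.nan)
    p = np.where(visited, occ_s, 0.0)
    p = p / p.sum()
    p = np.where(visited, p, np.nan)
    total_t = occ.sum()
    mean_rate = float(cnt.sum() / total_t) if total_t > 0 else np.nan
    x_edges, y_edges = _spatial_bins(arena, bin_size)
    return RateMap(x_edges, y_edges, rate, p, bin_size, sigma, mean_rate, visited)


def compute_rate_map(spikes: SpikeTrain, trajectory: Trajectory,
                     arena: ArenaSpec, mask=None, bin_size: float = 0.5,
                     sigma: float = 2.5) -> RateMap:
    """Occupancy-normalized spatial rate map (0.5 cm bins by default).

    Count and occupancy maps are smoothed *before* division, which avoids
    edge-rate inflation; sigma = 0 reproduces the raw count/occupancy ratio.
    """
    counts = spikes_to_frame_counts(spikes, trajectory)
    return rate_map_from_frame_counts(counts, trajectory, arena, mask,
                                      bin_size=bin_size, sigma=sigma)
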