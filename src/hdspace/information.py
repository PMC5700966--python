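"""Skaggs information, surrogate-corrected unbiased spatial information, and
cross-validated spatial information with kernel-scale selection.

The information carried by a rate function lambda(x) about a binned variable
x with occupancy probability p(x) is

    I = sum_x lambda(x) * log2(lambda(x) / lambda_bar) * p(x)    [bits/s]

with lambda_bar = sum_x lambda(x) p(x) and 0*log0 := 0; bits/spike is
I / lambda_bar. Spatial information computed this way is inflated for HD
cells by the position-dependent heading bias of the animal's behavior. The
correction generates control spike trains as Poisson processes driven only
by the cell's own HD tuning curve and the instantaneous heading, rebuilds
the rate map with the identical estimator, and subtracts the mean control
information: unbiased = observed - mean(surrogates), exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_core import ArenaSpec, SpikeTrain, Trajectory
from .tuning import (
    HDTuningCurve,
    hd_bin_index,
    rate_map_from_frame_counts,
    spatial_bin_index,
    spikes_to_frame_counts,
)

logger = logging.getLogger("hdspace")

#: number of HD-conditioned control trains per neuron
N_SURROGATES = 500

#: default smoothing for the headline spatial-information maps (cm), inside
#: the 2-4 cm scale at which real spike trains are best predicted
DEFAULT_MAP_SIGMA = 2.5

#: default kernel-scale grid for cross-validation (cm)
SIGMA_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 25.0)


@dataclass
class InfoResult:
    observed_bits_per_spike: float
    observed_bits_per_s: float
    surrogate_mean: float  # bits/spike
    surrogate_sd: float  # bits/spike
    n_surrogates: int
    unbiased_bits_per_spike: float


@dataclass
class CrossValInfo:
    sigma_grid: np.ndarray
    cv_score_per_sigma: np.ndarray  # bits/spike, fold mean
    best_sigma: float
    best_score: float
    n_folds: int


# ---------------------------------------------------------------------------
# Skaggs information
# ---------------------------------------------------------------------------

def skaggs_information(rate, occupancy_p):
    """Information of a binned rate function; nan bins are excluded jointly.

    Returns (bits/s, bits/spike); both nan when the mean rate is 0.
    """
    rate = np.asarray(rate, dtype=float).ravel()
    p = np.asarray(occupancy_p, dtype=float).ravel()
    ok = np.isfinite(rate) & np.isfinite(p)
    rate, p = rate[ok], p[ok]
    if np.any(rate < 0) or np.any(p < 0):
        raise ValueError("rates and probabilities must be non-negative")
    lam = float(np.sum(rate * p))
    if lam <= 0:
        return np.nan, np.nan
    pos = rate > 0
    bits_s = float(np.sum(p[pos] * rate[pos] * np.log2(rate[pos] / lam)))
    return bits_s, bits_s / lam


# ---------------------------------------------------------------------------
# HD-conditioned surrogates
# ---------------------------------------------------------------------------

def _hd_rate_per_frame(curve: HDTuningCurve, trajectory: Trajectory):
    """Tuning-curve rate at each frame's heading; undefined bins -> 0."""
    rate = curve.rate[hd_bin_index(trajectory.hd)]
    bad = ~np.isfinite(rate)
    if bad.any():
        logger.warning(
            "hd rate lookup: %d frames visit bins with undefined rate; "
            "substituting 0", int(bad.sum())
        )
        rate = np.where(bad, 0.0, rate)
    return rate


def surrogate_frame_counts(curve: HDTuningCurve, trajectory: Trajectory,
                           mask: Optional[np.ndarray] = None,
                           n: int = N_SURROGATES, seed: int = 0) -> np.ndarray:
    """(n, n_frames) Poisson counts driven only by heading and HD tuning.

    Off-mask frames get zero counts, matching how masked analyses treat the
    observed train.
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    mask = np.ones(trajectory.n, dtype=bool) if mask is None else np.asarray(mask)
    rng = np.random.default_rng(seed)
    lam = _hd_rate_per_frame(curve, trajectory) * trajectory.frame_dt()
    lam = np.where(mask, lam, 0.0)
    return rng.poisson(lam, size=(n, trajectory.n))


def surrogate_spike_trains(curve: HDTuningCurve, trajectory: Trajectory,
                           mask: Optional[np.ndarray] = None,
                           n: int = N_SURROGATES, seed: int = 0):
    """Control spike trains as explicit timestamp lists (times jittered
    uniformly within each frame)."""
    counts = surrogate_frame_counts(curve, trajectory, mask, n, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    dtf = trajectory.frame_dt()
    trains = []
    for i in range(n):
        total = int(counts[i].sum())
        starts = np.repeat(trajectory.t, counts[i])
        widths = np.repeat(dtf, counts[i])
        trains.append(SpikeTrain(f"surrogate{i:03d}", starts + rng.random(total) * widths))
    return trains


def unbiased_spatial_information(spikes: SpikeTrain, curve: HDTuningCurve,
                                 trajectory: Trajectory, arena: ArenaSpec,
                                 mask: Optional[np.ndarray] = None,
                                 n: int = N_SURROGATES, seed: int = 0,
                                 bin_size: float = 0.5,
                                 sigma: float = DEFAULT_MAP_SIGMA) -> InfoResult:
    """Observed spatial information minus the mean over HD-matched surrogates.

    Observed and surrogate rate maps use the identical estimator (same bins,
    same smoothing, same occupancy), so the subtraction removes exactly the
    component of spatial information attributable to HD tuning plus the
    heading bias of behavior (and the finite-sampling bias they share).
    """
    obs_map = rate_map_from_frame_counts(
        spikes_to_frame_counts(spikes, trajectory), trajectory, arena, mask,
        bin_size=bin_size, sigma=sigma,
    )
    obs_s, obs_spk = skaggs_information(obs_map.rate, obs_map.occupancy_p)
    counts = surrogate_frame_counts(curve, trajectory, mask, n, seed)
    vals = np.empty(n)
    for i in range(n):
        m = rate_map_from_frame_counts(counts[i], trajectory, arena, mask,
                                       bin_size=bin_size, sigma=sigma)
        vals[i] = skaggs_information(m.rate, m.occupancy_p)[1]
    vals = vals[np.isfinite(vals)]
    mean = float(vals.mean()) if vals.size else np.nan
    sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
    return InfoResult(obs_spk, obs_s, mean, sd, n, obs_spk - mean)


# ---------------------------------------------------------------------------
# cross-validated information
# ---------------------------------------------------------------------------

def cross_validated_information(spikes: SpikeTrain, trajectory: Trajectory,
                                arena: ArenaSpec,
                                mask: Optional[np.ndarray] = None,
                                sigma_grid: Sequence[float] = SIGMA_GRID,
                                n_folds: int = 10, bin_size: float = 0.5,
                                seed: int = 0) -> CrossValInfo:
    """Spatial information by cross-validated Poisson prediction.

    The trajectory is partitioned into contiguous time blocks (respecting
    temporal autocorrelation). Per fold and smoothing scale, the training
    rate map predicts the per-frame rate of the held-out block; the score is
    the Poisson log-likelihood gain over the homogeneous mean-rate model, in
    bits per test spike. ``seed`` is accepted for interface stability; the
    block partition is deterministic.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    mask = np.ones(trajectory.n, dtype=bool) if mask is None else np.asarray(mask)
    frame_counts = spikes_to_frame_counts(spikes, trajectory)
    flat, _ = spatial_bin_index(trajectory, arena, bin_size)
    dtf = trajectory.frame_dt()
    blocks = np.array_split(np.arange(trajectory.n), n_folds)
    scores = np.zeros((n_folds, sigma_grid.size))
    used = np.zeros(n_folds, dtype=bool)
    for f, test_idx in enumerate(blocks):
        test = np.zeros(trajectory.n, dtype=bool)
        test[test_idx] = True
        tr_mask = mask & ~test
        te = mask & test
        y = frame_counts[te]
        if y.sum() == 0 or tr_mask.sum() == 0:
            logger.info("cv fold %d skipped (no test spikes)", f)
            continue
        used[f] = True
        lam0 = frame_counts[tr_mask].sum() / dtf[tr_mask].sum()
        for j, sig in enumerate(sigma_grid):
            rm = rate_map_from_frame_counts(frame_counts, trajectory, arena,
                                            tr_mask, bin_size=bin_size,
                                            sigma=sig)
            pred = rm.rate.ravel()[flat[te]]
            pred = np.where(np.isfinite(pred), pred, lam0)
            pred = np.clip(pred, lam0 * 1e-3, None)
            ll = np.sum(y * np.log(pred / lam0)) - np.sum((pred - lam0) * dtf[te])
            scores[f, j] = ll / np.log(2) / y.sum()
    if not used.any():
        raise ValueError("no usable folds")
    cv = scores[used].mean(axis=0)
    best = int(np.argmax(cv))
    return CrossValInfo(sigma_grid, cv, float(sigma_grid[best]), float(cv[best]),
                        int(used.sum()))
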