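"""Poisson regression of spike trains on border and egocentric variables.

Spike trains are binned at 5 ms, smoothed with a Gaussian filter (sd
25.6 ms, one video frame), and regressed with a log link on z-scored
observables:

    lambda_i(t) = exp(beta_{i,0} + sum_k beta_{i,k} X_k(t))

Two separate regressions are fitted per cell, each including the expected
instantaneous firing rate from the HD tuning curve as a covariate:

- border: four binary wall-proximity variables (within 15 cm of one wall,
  corners excluded). Border modulation = the maximal wall coefficient; a
  cell is border-modulated when it exceeds 0.1.
- egocentric: two binary variables flagging a nearest wall (<= 15 cm) within
  +-60 deg of the left or right body axis. Egocentric modulation = the
  absolute difference of the two coefficients.

z-scoring the regressors (including the binary ones) makes the coefficients
comparable across cells and independent of firing rate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special
from scipy.ndimage import gaussian_filter1d

from .circular import wrap_pi
from .io_core import ArenaSpec, Session, Trajectory, speed_filter
from .tuning import HDTuningCurve, compute_hd_tuning, hd_bin_index

logger = logging.getLogger("hdspace")

BIN_MS = 5.0
SMOOTH_SD_MS = 25.6
WALL_DISTANCE_CM = 15.0
EGO_HALF_WINDOW_DEG = 60.0
BORDER_THRESHOLD = 0.1
MIN_SPIKES = 100

WALL_COLUMNS = ("east", "north", "west", "south")
EGO_COLUMNS = ("wall_left", "wall_right")
HD_RATE_COLUMN = "hd_expected_rate"


@dataclass
class GLMFit:
    beta0: float
    beta: dict  # column name -> coefficient
    converged: bool
    n_iter: int
    deviance: float


@dataclass
class ModulationScores:
    cell_id: str
    fit: GLMFit
    border_modulation: float = np.nan
    best_wall: Optional[str] = None
    is_border_modulated: Optional[bool] = None
    egocentric_modulation: float = np.nan
    degenerate_columns: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# binning / smoothing
# ---------------------------------------------------------------------------

def time_bins(t_start: float, t_stop: float, bin_ms: float = BIN_MS):
    """Edges and centers of the regression time grid."""
    if t_stop <= t_start:
        raise ValueError("empty time span")
    width = bin_ms / 1000.0
    n = int(np.ceil((t_stop - t_start) / width))
    edges = t_start + np.arange(n + 1) * width
    return edges, (edges[:-1] + edges[1:]) / 2.0


def bin_and_smooth_spikes(spike_times, t_start: float, t_stop: float,
                          bin_ms: float = BIN_MS,
                          smooth_sd_ms: float = SMOOTH_SD_MS) -> np.ndarray:
    """Per-bin spike counts convolved with a normalized Gaussian kernel
    (truncated at +-4 sd, symmetric boundary); total count is conserved."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    edges, _ = time_bins(t_start, t_stop, bin_ms)
    counts, _ = np.histogram(spike_times, bins=edges)
    counts = counts.astype(float)
    if smooth_sd_ms <= 0:
        return counts
    return gaussian_filter1d(counts, smooth_sd_ms / bin_ms, mode="reflect",
                             truncate=4.0)


def frames_to_bins(values: np.ndarray, trajectory: Trajectory, bin_centers):
    """Hold per-frame values constant across the 5 ms bins each frame spans."""
    idx = trajectory.frame_index(bin_centers)
    return np.asarray(values)[..., idx]


# ---------------------------------------------------------------------------
# regressors (per tracking frame)
# ---------------------------------------------------------------------------

def build_border_regressors(trajectory: Trajectory, arena: ArenaSpec,
                            wall_distance_cm: float = WALL_DISTANCE_CM):
    """Four binary wall series, shape (4, n_frames), order E/N/W/S.

    A wall flag is 1 iff the animal is within wall_distance of that wall and
    at least wall_distance from every other wall; in the four corners (two
    walls close) all flags are 0.
    """
    if wall_distance_cm >= min(arena.width, arena.height) / 2.0:
        raise ValueError("wall distance too large for this arena")
    d = arena.wall_distances(trajectory.x, trajectory.y)
    near = d < wall_distance_cm
    exclusive = near & (near.sum(axis=0) == 1)
    return exclusive.astype(float)


def build_egocentric_regressors(trajectory: Trajectory, arena: ArenaSpec,
                                wall_distance_cm: float = WALL_DISTANCE_CM,
                                half_window_deg: float = EGO_HALF_WINDOW_DEG):
    """Two binary series (wall_left, wall_right), shape (2, n_frames).

    phi is the signed angle from the head direction to the bearing of the
    nearest point of the nearest wall (perpendicular foot). wall_left = 1
    iff phi is within half_window of +90 deg, wall_right within half_window
    of -90 deg; both 0 when no wall is within wall_distance.
    """
    if not (0 < half_window_deg < 90):
        raise ValueError("half window must be in (0, 90) degrees")
    widx, dist = arena.nearest_wall(trajectory.x, trajectory.y)
    near = dist <= wall_distance_cm
    bearing = arena.wall_bearings[widx]
    phi = wrap_pi(bearing - trajectory.hd)
    half = np.deg2rad(half_window_deg)
    left = near & (np.abs(wrap_pi(phi - np.pi / 2)) <= half)
    right = near & (np.abs(wrap_pi(phi + np.pi / 2)) <= half)
    return np.stack([left, right]).astype(float)


def hd_expected_rate_regressor(curve: HDTuningCurve, trajectory: Trajectory):
    """Expected instantaneous rate from the HD tuning curve at each frame's
    heading (undefined bins -> 0, logged)."""
    rate = curve.rate[hd_bin_index(trajectory.hd)]
    bad = ~np.isfinite(rate)
    if bad.any():
        logger.warning("hd_expected_rate: %d frames in undefined bins -> 0",
                       int(bad.sum()))
    return np.where(bad, 0.0, rate)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def zscore_columns(X: np.ndarray):
    """Z-score columns; constant columns become all-zero and are reported."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd <= 0
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, degenerate] = 0.0
    return Z, np.nonzero(degenerate)[0]


def _poisson_deviance(y, mu):
    # quasi-likelihood deviance; well-defined for non-integer y >= 0
    return float(2.0 * np.sum(special.xlogy(y, y / mu) - (y - mu)))


def fit_poisson_glm(y: np.ndarray, X: np.ndarray, names=None,
                    max_iter: int = 100, tol: float = 1e-8,
                    ridge: float = 0.0) -> GLMFit:
    """Maximize the (continuous-response) Poisson log-likelihood with a log
    link by iteratively reweighted least squares.

    ``y`` may be non-integer after smoothing; columns of ``X`` are assumed
    z-scored. With no columns the intercept is log(mean(y)). Convergence:
    relative deviance change < 1e-8 or 100 iterations; on numerical failure
    the fit is retried with a small ridge (1e-6) and flagged.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be non-negative")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mean = y.mean()
    if X.shape[1] == 0:
        return GLMFit(float(np.log(mean)) if mean > 0 else -np.inf, {}, True, 0,
                      _poisson_deviance(y, max(mean, 1e-300)))
    names = list(names) if names is not None else \
        [f"x{k}" for k in range(X.shape[1])]
    design = np.column_stack([np.ones(y.size), X])
    ncol = design.shape[1]
    beta = np.zeros(ncol)
    beta[0] = np.log(mean) if mean > 0 else -10.0
    eta = design @ beta
    dev = np.inf
    converged = False
    penalty = ridge * np.eye(ncol)
    penalty[0, 0] = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        z = eta + (y - mu) / mu
        wd = design * mu[:, None]
        try:
            beta = np.linalg.solve(wd.T @ design + penalty, wd.T @ z)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                logger.warning("GLM normal equations singular; "
                               "refitting with ridge 1e-6")
                fit = fit_poisson_glm(y, X, names, max_iter, tol, ridge=1e-6)
                fit.converged = False
                return fit
            raise
        eta = design @ beta
        new_dev = _poisson_deviance(y, np.exp(np.clip(eta, -30.0, 30.0)))
        if np.isfinite(new_dev) and abs(dev - new_dev) <= tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not np.all(np.isfinite(beta)):
        logger.warning("GLM produced non-finite coefficients; flagged")
        converged = False
    if not converged:
        logger.warning("GLM did not converge in %d iterations", max_iter)
    return GLMFit(float(beta[0]), dict(zip(names, beta[1:])), converged,
                  n_iter, dev)


# ---------------------------------------------------------------------------
# per-cell modulation scores
# ---------------------------------------------------------------------------

def _analysis_bins(session: Session, mask, bin_ms):
    """Bin grid over the session plus the boolean selector of analyzed bins
    (speed-masked wake)."""
    traj = session.trajectory
    edges, centers = time_bins(traj.t[0], traj.t[-1] + traj.frame_dt()[-1], bin_ms)
    sel = frames_to_bins(mask.astype(float), traj, centers) > 0.5
    wake = session.epoch("wake")
    if wake is not None:
        sel &= wake.contains(centers)
    return edges, centers, sel


def _fit_modulation(session: Session, cell_id: str, columns, names,
                    curve: HDTuningCurve, mask, bin_ms, smooth_sd_ms):
    traj = session.trajectory
    train = session.spike_train(cell_id)
    edges, centers, sel = _analysis_bins(session, mask, bin_ms)
    y_all = bin_and_smooth_spikes(train.times, traj.t[0], edges[-1], bin_ms,
                                  smooth_sd_ms)
    hd_rate = hd_expected_rate_regressor(curve, traj)
    per_frame = np.vstack([columns, hd_rate[None, :]])
    Xb = frames_to_bins(per_frame, traj, centers).T
    y = y_all[sel]
    if y.sum() < MIN_SPIKES:
        raise ValueError(
            f"cell {cell_id}: fewer than {MIN_SPIKES} spikes in masked wake data"
        )
    Z, degenerate = zscore_columns(Xb[sel])
    if degenerate.size:
        logger.warning("cell %s: constant regressors %s", cell_id,
                       [names[i] for i in degenerate])
    fit = fit_poisson_glm(y, Z, names=list(names) + [HD_RATE_COLUMN])
    return fit, tuple(names[i] for i in degenerate)


def border_modulation(session: Session, cell_id: str,
                      curve: Optional[HDTuningCurve] = None,
                      mask: Optional[np.ndarray] = None,
                      wall_distance_cm: float = WALL_DISTANCE_CM,
                      bin_ms: float = BIN_MS,
                      smooth_sd_ms: float = SMOOTH_SD_MS,
                      threshold: float = BORDER_THRESHOLD) -> ModulationScores:
    """Fit the border regression and summarize wall modulation."""
    traj = session.trajectory
    mask = speed_filter(traj) if mask is None else np.asarray(mask)
    if curve is None:
        curve = compute_hd_tuning(session.spike_train(cell_id), traj, mask)
    cols = build_border_regressors(traj, session.arena, wall_distance_cm)
    fit, degenerate = _fit_modulation(session, cell_id, cols, WALL_COLUMNS,
                                      curve, mask, bin_ms, smooth_sd_ms)
    wall_betas = {w: fit.beta[w] for w in WALL_COLUMNS}
    best_wall = max(wall_betas, key=wall_betas.get)
    border = float(wall_betas[best_wall])
    return ModulationScores(
        cell_id=cell_id, fit=fit, border_modulation=border, best_wall=best_wall,
        is_border_modulated=bool(border > threshold),
        degenerate_columns=degenerate,
    )


def egocentric_modulation(session: Session, cell_id: str,
                          curve: Optional[HDTuningCurve] = None,
                          mask: Optional[np.ndarray] = None,
                          wall_distance_cm: float = WALL_DISTANCE_CM,
                          half_window_deg: float = EGO_HALF_WINDOW_DEG,
                          bin_ms: float = BIN_MS,
                          smooth_sd_ms: float = SMOOTH_SD_MS) -> ModulationScores:
    """Fit the egocentric regression; score = |beta_left - beta_right|."""
    traj = session.trajectory
    mask = speed_filter(traj) if mask is None else np.asarray(mask)
    if curve is None:
        curve = compute_hd_tuning(session.spike_train(cell_id), traj, mask)
    cols = build_egocentric_regressors(traj, session.arena, wall_distance_cm,
                                       half_window_deg)
    fit, degenerate = _fit_modulation(session, cell_id, cols, EGO_COLUMNS,
                                      curve, mask, bin_ms, smooth_sd_ms)
    score = float(abs(fit.beta["wall_left"] - fit.beta["wall_right"]))
    return ModulationScores(cell_id=cell_id, fit=fit,
                            egocentric_modulation=score,
                            degenerate_columns=degenerate)
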