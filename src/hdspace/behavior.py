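"""Position-dependent orientation bias of heading.

Heading angles are doubled (mod 2*pi) so that opposite directions collapse
onto one orientation — 90 deg and 270 deg both become 180 deg — then, per
spatial bin, the resultant of the doubled angles gives the mean orientation
(resultant direction / 2) and a von Mises concentration via the A(kappa)
inversion. Near walls, ambulation is constrained to run parallel to them,
so the wall band shows systematically higher concentration than the
interior: this is the behavioral bias that injects spurious spatial
information into pure HD cells.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .circular import TWO_PI, kappa_from_resultant
from .io_core import ArenaSpec, Trajectory

#: default spatial bin (cm); coarser than rate maps for stable per-bin
#: circular statistics
BIAS_BIN_CM = 2.0

#: kappa cap: the A(kappa) inversion diverges as the resultant length -> 1
KAPPA_CAP = 50.0

MIN_SAMPLES_PER_BIN = 10


@dataclass
class OrientationBiasMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_orientation: np.ndarray  # (nx, ny) rad in [0, pi), nan where undefined
    concentration: np.ndarray  # (nx, ny) kappa of doubled angles
    occupancy_s: np.ndarray
    n_samples: np.ndarray
    capped: np.ndarray  # bins where kappa hit the cap
    bin_size: float


def orientation_bias_map(trajectory: Trajectory, arena: ArenaSpec,
                         mask: Optional[np.ndarray] = None,
                         bin_cm: float = BIAS_BIN_CM,
                         min_samples: int = MIN_SAMPLES_PER_BIN,
                         kappa_cap: float = KAPPA_CAP) -> OrientationBiasMap:
    """Per-spatial-bin circular statistics of doubled headings."""
    if trajectory.n == 0:
        raise ValueError("empty trajectory")
    mask = np.ones(trajectory.n, dtype=bool) if mask is None else np.asarray(mask)
    if not mask.any():
        raise ValueError("empty mask")
    nx = int(np.ceil(arena.width / bin_cm))
    ny = int(np.ceil(arena.height / bin_cm))
    ix = np.clip((trajectory.x[mask] // bin_cm).astype(np.int64), 0, nx - 1)
    iy = np.clip((trajectory.y[mask] // bin_cm).astype(np.int64), 0, ny - 1)
    flat = ix * ny + iy
    doubled = np.mod(2.0 * trajectory.hd[mask], TWO_PI)
    dtf = trajectory.frame_dt()[mask]

    nbins = nx * ny
    n = np.bincount(flat, minlength=nbins)
    occ = np.bincount(flat, weights=dtf, minlength=nbins)
    c = np.bincount(flat, weights=np.cos(doubled), minlength=nbins)
    s = np.bincount(flat, weights=np.sin(doubled), minlength=nbins)

    ok = n >= min_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.hypot(c, s) / np.where(n > 0, n, 1)
    mean_orient = np.mod(np.arctan2(s, c), TWO_PI) / 2.0
    kappa = np.array([kappa_from_resultant(ri, cap=kappa_cap) for ri in r])
    capped = ok & (kappa >= kappa_cap)
    mean_orient = np.where(ok, mean_orient, np.nan)
    kappa = np.where(ok, kappa, np.nan)

    shape = (nx, ny)
    return OrientationBiasMap(
        x_edges=np.arange(nx + 1) * bin_cm,
        y_edges=np.arange(ny + 1) * bin_cm,
        mean_orientation=mean_orient.reshape(shape),
        concentration=kappa.reshape(shape),
        occupancy_s=occ.reshape(shape),
        n_samples=n.reshape(shape),
        capped=capped.reshape(shape),
        bin_size=bin_cm,
    )


def wall_band_mask(bias_map: OrientationBiasMap, arena: ArenaSpec,
                   band_cm: float = 15.0) -> np.ndarray:
    """Boolean (nx, ny) mask of bins whose center lies within band_cm of a
    wall."""
    xc = (bias_map.x_edges[:-1] + bias_map.x_edges[1:]) / 2.0
    yc = (bias_map.y_edges[:-1] + bias_map.y_edges[1:]) / 2.0
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    d = np.minimum.reduce([X, arena.width - X, Y, arena.height - Y])
    return d < band_cm
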