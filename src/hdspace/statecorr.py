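"""Cross-state preservation of pairwise HD-cell co-firing.

Rates are binned (1 s default) within wake / REM / non-REM epochs; Pearson
correlations of z-scored rate series give one correlation per cell pair per
state. Pairs are stratified by the mean unbiased spatial information of
their two cells (bottom / top 33rd percentile), and preservation is the
correlation, across pairs, between wake and sleep pair-correlations. Groups
are compared with the Fisher z test on the two
correlation-of-correlations coefficients: rigidly (internally) coordinated
HD populations preserve their wake structure during sleep, spatially
modulated ones less so.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, pearsonr

from .io_core import Session, SpikeTrain, EpochSet, speed_filter

logger = logging.getLogger("hdspace")

CORR_BIN_S = 1.0
PERCENTILE = 33.0

GROUP_BOTTOM = "bottom33"
GROUP_MIDDLE = "middle"
GROUP_TOP = "top33"


@dataclass
class PairCorrelation:
    cell_pair: tuple
    r_wake: float = np.nan
    r_rem: float = np.nan
    r_nrem: float = np.nan
    group: Optional[str] = None

    def r_state(self, state: str) -> float:
        return {"wake": self.r_wake, "rem": self.r_rem, "nrem": self.r_nrem}[state]


@dataclass
class GroupComparison:
    state: str
    r_across_a: float
    r_across_b: float
    n_a: int
    n_b: int
    z: float
    p: float
    ci95_a: tuple
    ci95_b: tuple


# ---------------------------------------------------------------------------
# binned rates
# ---------------------------------------------------------------------------

def epoch_bin_edges(epochs: EpochSet, bin_s: float):
    """Left edges of bins fully inside the epoch intervals, on the global
    grid anchored at t = 0; bins straddling interval edges are dropped."""
    if bin_s <= 0:
        raise ValueError("bin size must be positive")
    lefts = []
    for s, e in epochs.intervals:
        k0 = int(np.ceil(s / bin_s - 1e-9))
        k1 = int(np.floor(e / bin_s + 1e-9))
        if k1 > k0:
            lefts.append(np.arange(k0, k1) * bin_s)
    if not lefts:
        raise ValueError(f"epoch '{epochs.label}' covers no complete bin")
    return np.concatenate(lefts)


def binned_rates(spikes: SpikeTrain, epochs: EpochSet, bin_s: float = CORR_BIN_S):
    """(bin left edges, rate per bin in Hz) restricted to the epochs."""
    lefts = epoch_bin_edges(epochs, bin_s)
    lo = np.searchsorted(spikes.times, lefts, side="left")
    hi = np.searchsorted(spikes.times, lefts + bin_s, side="left")
    return lefts, (hi - lo) / bin_s


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------

def _zscore(v):
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.full_like(v, np.nan)


def pairwise_correlations(session: Session, cell_ids: Optional[Sequence] = None,
                          bin_s: float = CORR_BIN_S,
                          wake_movement_only: bool = True):
    """Pearson correlation of binned, z-scored rates per pair per state.

    Wake bins are restricted to movement (majority of frames above the speed
    threshold); sleep states use all epoch bins. Pairs involving a
    zero-variance series in some state get nan there (flagged).
    """
    ids = list(cell_ids) if cell_ids is not None else session.cell_ids
    if len(ids) < 2:
        raise ValueError("need at least two cells")
    states = [e.label for e in session.epochs]
    series = {}
    for state in states:
        epochs = session.epoch(state)
        keep = None
        if state == "wake" and wake_movement_only:
            mask = speed_filter(session.trajectory)
            lefts = epoch_bin_edges(epochs, bin_s)
            traj = session.trajectory
            frac = []
            for left in lefts:
                sel = (traj.t >= left) & (traj.t < left + bin_s)
                frac.append(mask[sel].mean() if sel.any() else 0.0)
            keep = np.asarray(frac) > 0.5
        for cid in ids:
            _, rate = binned_rates(session.spike_train(cid), epochs, bin_s)
            series[(state, cid)] = _zscore(rate[keep] if keep is not None else rate)

    pairs = []
    for a, b in combinations(ids, 2):
        pc = PairCorrelation(cell_pair=(a, b))
        for state in states:
            va, vb = series[(state, a)], series[(state, b)]
            if np.isnan(va).any() or np.isnan(vb).any() or va.size < 3:
                r = np.nan
            else:
                r = float(pearsonr(va, vb)[0])
            setattr(pc, f"r_{state}", r)
        pairs.append(pc)
    return pairs


# ---------------------------------------------------------------------------
# stratification and group comparison
# ---------------------------------------------------------------------------

def percentile_groups(pairs: Sequence[PairCorrelation], unbiased_info_per_cell: dict,
                      pct: float = PERCENTILE):
    """Label pairs bottom/top by the percentile of the pair score (mean of
    the two cells' unbiased spatial information). Mutates and returns pairs."""
    if not (0 < pct <= 50):
        raise ValueError("pct must be in (0, 50]")
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    scores = np.array([
        (unbiased_info_per_cell[a] + unbiased_info_per_cell[b]) / 2.0
        for a, b in (p.cell_pair for p in pairs)
    ])
    if np.ptp(scores) == 0:
        logger.warning("percentile_groups: all pair scores tied; "
                       "filling groups in stable order")
        k = int(round(len(pairs) * pct / 100.0))
        for i, p in enumerate(pairs):
            p.group = (GROUP_BOTTOM if i < k
                       else GROUP_TOP if i >= len(pairs) - k else GROUP_MIDDLE)
        return pairs
    lo = np.quantile(scores, pct / 100.0)
    hi = np.quantile(scores, 1.0 - pct / 100.0)
    for p, sc in zip(pairs, scores):
        p.group = (GROUP_BOTTOM if sc <= lo
                   else GROUP_TOP if sc >= hi else GROUP_MIDDLE)
    return pairs


def _fisher_ci(r, n):
    if n <= 3 or not np.isfinite(r) or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def compare_preservation(pairs: Sequence[PairCorrelation], group_a: str,
                         group_b: str, state: str) -> GroupComparison:
    """Fisher z comparison of wake-vs-``state`` preservation between groups.

    Per group, preservation is the Pearson correlation, across its pairs,
    between r_wake and r_state; the two coefficients are compared with the
    independent-samples Fisher z test (two-sided).
    """
    def group_r(label):
        sel = [p for p in pairs
               if p.group == label
               and np.isfinite(p.r_wake) and np.isfinite(p.r_state(state))]
        if len(sel) < 4:
            raise ValueError(f"group '{label}': fewer than 4 usable pairs")
        w = np.array([p.r_wake for p in sel])
        s = np.array([p.r_state(state) for p in sel])
        if w.std() == 0 or s.std() == 0:
            logger.warning("group '%s': degenerate variance", label)
            return np.nan, len(sel)
        return float(pearsonr(w, s)[0]), len(sel)

    r_a, n_a = group_r(group_a)
    r_b, n_b = group_r(group_b)
    if np.isfinite(r_a) and np.isfinite(r_b):
        denom = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
        z = (np.arctanh(np.clip(r_a, -1 + 1e-12, 1 - 1e-12))
             - np.arctanh(np.clip(r_b, -1 + 1e-12, 1 - 1e-12))) / denom
        p = float(2.0 * norm.sf(abs(z)))
    else:
        z, p = np.nan, np.nan
    return GroupComparison(state, r_a, r_b, n_a, n_b, float(z), p,
                           _fisher_ci(r_a, n_a), _fisher_ci(r_b, n_b))
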