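"""End-to-end orchestration: tuning -> information -> glm -> behavior ->
statecorr, with per-stage CSV outputs and a summary.json.

All stage defaults are the analysis constants of the study design (speed
threshold 2.5 cm/s, 6 deg HD bins, 1000 shuffles at p <= 0.001, split-half
r > 0.75, kappa > 1, 0.5 cm spatial bins smoothed at 2.5 cm, 500 surrogates,
5 ms GLM bins smoothed at 25.6 ms, 15 cm wall distance, +-60 deg egocentric
window, border threshold 0.1, 33rd percentile split). Runs with identical
configuration and seeds are byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import behavior, glm, information, statecorr, tuning
from .celltype import classify_cell_type
from .io_core import Session, epoch_view, read_session, speed_filter

logger = logging.getLogger("hdspace")


class PipelineStageError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    speed_threshold: float = 2.5  # cm/s
    hd_bin_deg: float = 6.0
    n_shuffles: int = 1000
    shuffle_p: float = 0.001
    stability_r: float = 0.75
    kappa_min: float = 1.0
    spatial_bin_cm: float = 0.5
    map_sigma_cm: float = 2.5
    n_surrogates: int = 500
    run_cv: bool = True
    cv_sigma_grid: tuple = information.SIGMA_GRID
    cv_folds: int = 10
    glm_bin_ms: float = 5.0
    glm_smooth_ms: float = 25.6
    wall_distance_cm: float = 15.0
    ego_half_window_deg: float = 60.0
    border_threshold: float = 0.1
    percentile: float = 33.0
    corr_bin_s: float = 1.0
    bias_bin_cm: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def _wake_view(session, cfg):
    """Trajectory, movement mask and spike trains of the wake epoch (the
    whole session when no wake epoch is present)."""
    if session.epoch("wake") is not None:
        traj, spikes = epoch_view(session, "wake")
    else:
        traj, spikes = session.trajectory, session.spikes
    mask = speed_filter(traj, cfg.speed_threshold)
    return traj, mask, {s.cell_id: s for s in spikes}


@_stage("tuning")
def _run_tuning(session, wake, cfg):
    traj, mask, spikes = wake
    rows = []
    curves = {}
    for i, cid in enumerate(session.cell_ids):
        train = spikes[cid]
        if train.n == 0:
            raise ValueError(f"cell {cid} has no spikes")
        curves[cid] = tuning.compute_hd_tuning(train, traj, mask)
        cls = tuning.classify_hd_cell(
            train, traj, mask, seed=cfg.seed + i,
            n_shuffles=cfg.n_shuffles, p_threshold=cfg.shuffle_p,
            r_threshold=cfg.stability_r, kappa_threshold=cfg.kappa_min,
        )
        rows.append({
            "cell_id": cid,
            "is_hd": cls.is_hd,
            "shuffle_p": cls.shuffle_p,
            "split_half_r": cls.split_half_r,
            "concentration": cls.concentration,
            "preferred_direction_deg": np.rad2deg(cls.preferred_direction),
            "resultant_length": cls.resultant_length,
        })
    return pd.DataFrame(rows), curves


@_stage("information")
def _run_information(session, wake, curves, cfg):
    traj, mask, spikes = wake
    rows = []
    for i, cid in enumerate(session.cell_ids):
        train = spikes[cid]
        hd_bits = information.skaggs_information(
            curves[cid].rate,
            curves[cid].occupancy_s / curves[cid].occupancy_s.sum(),
        )[1]
        res = information.unbiased_spatial_information(
            train, curves[cid], traj, session.arena, mask,
            n=cfg.n_surrogates, seed=cfg.seed + 1000 + i,
            bin_size=cfg.spatial_bin_cm, sigma=cfg.map_sigma_cm,
        )
        row = {
            "cell_id": cid,
            "hd_info_bits_per_spike": hd_bits,
            "spatial_info_bits_per_spike": res.observed_bits_per_spike,
            "surrogate_mean": res.surrogate_mean,
            "surrogate_sd": res.surrogate_sd,
            "unbiased_bits_per_spike": res.unbiased_bits_per_spike,
        }
        if cfg.run_cv:
            cv = information.cross_validated_information(
                train, traj, session.arena, mask,
                sigma_grid=cfg.cv_sigma_grid, n_folds=cfg.cv_folds,
                bin_size=cfg.spatial_bin_cm,
            )
            row["cv_best_sigma_cm"] = cv.best_sigma
            row["cv_best_score"] = cv.best_score
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("glm")
def _run_glm(session, mask, curves, cfg):
    rows = []
    for cid in session.cell_ids:
        try:
            bm = glm.border_modulation(
                session, cid, curves[cid], mask,
                wall_distance_cm=cfg.wall_distance_cm, bin_ms=cfg.glm_bin_ms,
                smooth_sd_ms=cfg.glm_smooth_ms, threshold=cfg.border_threshold,
            )
            em = glm.egocentric_modulation(
                session, cid, curves[cid], mask,
                wall_distance_cm=cfg.wall_distance_cm,
                half_window_deg=cfg.ego_half_window_deg,
                bin_ms=cfg.glm_bin_ms, smooth_sd_ms=cfg.glm_smooth_ms,
            )
        except ValueError as exc:  # too few spikes
            logger.warning("glm: skipping %s (%s)", cid, exc)
            rows.append({"cell_id": cid})
            continue
        rows.append({
            "cell_id": cid,
            **{f"beta_{w}": bm.fit.beta[w] for w in glm.WALL_COLUMNS},
            "beta_hd_rate": bm.fit.beta[glm.HD_RATE_COLUMN],
            "border_modulation": bm.border_modulation,
            "best_wall": bm.best_wall,
            "is_border_modulated": bm.is_border_modulated,
            "beta_left": em.fit.beta["wall_left"],
            "beta_right": em.fit.beta["wall_right"],
            "egocentric_modulation": em.egocentric_modulation,
        })
    return pd.DataFrame(rows)


@_stage("behavior")
def _run_behavior(session, wake, cfg):
    traj, mask, _ = wake
    bm = behavior.orientation_bias_map(traj, session.arena, mask,
                                       bin_cm=cfg.bias_bin_cm)
    nx, ny = bm.concentration.shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return pd.DataFrame({
        "x_cm": (ix.ravel() + 0.5) * bm.bin_size,
        "y_cm": (iy.ravel() + 0.5) * bm.bin_size,
        "mean_orientation_deg": np.rad2deg(bm.mean_orientation.ravel()),
        "concentration": bm.concentration.ravel(),
        "occupancy_s": bm.occupancy_s.ravel(),
        "n_samples": bm.n_samples.ravel(),
    })


@_stage("statecorr")
def _run_statecorr(session, info_df, tuning_df, cfg):
    states = {e.label for e in session.epochs}
    hd_ids = tuning_df.loc[tuning_df["is_hd"], "cell_id"].tolist()
    if len(hd_ids) < 2 or not ({"rem", "nrem"} & states):
        logger.info("statecorr skipped: needs >=2 HD cells and sleep epochs")
        return pd.DataFrame(), {}
    pairs = statecorr.pairwise_correlations(session, hd_ids, bin_s=cfg.corr_bin_s)
    info = dict(zip(info_df["cell_id"], info_df["unbiased_bits_per_spike"]))
    comparisons = {}
    if len(pairs) >= 3:
        statecorr.percentile_groups(pairs, info, pct=cfg.percentile)
        for state in sorted({"rem", "nrem"} & states):
            try:
                cmp_res = statecorr.compare_preservation(
                    pairs, statecorr.GROUP_BOTTOM, statecorr.GROUP_TOP, state)
                comparisons[state] = {
                    "r_bottom": cmp_res.r_across_a, "r_top": cmp_res.r_across_b,
                    "z": cmp_res.z, "p": cmp_res.p,
                    "n_bottom": cmp_res.n_a, "n_top": cmp_res.n_b,
                }
            except ValueError as exc:
                logger.info("statecorr comparison (%s) skipped: %s", state, exc)
    df = pd.DataFrame([{
        "cell_a": p.cell_pair[0], "cell_b": p.cell_pair[1],
        "r_wake": p.r_wake, "r_rem": p.r_rem, "r_nrem": p.r_nrem,
        "group": p.group,
    } for p in pairs])
    return df, comparisons


def _summary(session, tuning_df, info_df, glm_df, comparisons, cfg):
    merged = tuning_df.merge(info_df, on="cell_id")
    if not glm_df.empty:
        merged = merged.merge(glm_df, on="cell_id", how="left")
    if "is_border_modulated" not in merged:
        merged["is_border_modulated"] = False
    merged["is_border_modulated"] = merged["is_border_modulated"].fillna(False)
    is_hd = merged["is_hd"].to_numpy(bool)
    is_border = merged["is_border_modulated"].to_numpy(bool)
    cell_types = {
        cid: classify_cell_type(wf)
        for cid, wf in session.waveform_features.items()
    }

    def med(sel, col="unbiased_bits_per_spike"):
        v = merged.loc[sel, col].dropna()
        return float(v.median()) if len(v) else None

    hd_info = merged.loc[is_hd, "unbiased_bits_per_spike"].dropna()
    non_info = merged.loc[~is_hd, "unbiased_bits_per_spike"].dropna()
    mw_p = None
    if len(hd_info) >= 3 and len(non_info) >= 3:
        mw_p = float(mannwhitneyu(hd_info, non_info).pvalue)
    return {
        "n_cells": int(len(merged)),
        "n_hd": int(is_hd.sum()),
        "n_border_modulated": int(is_border.sum()),
        "n_hd_border": int((is_hd & is_border).sum()),
        "median_unbiased_info": {
            "hd": med(is_hd),
            "hd_border": med(is_hd & is_border),
            "hd_nonborder": med(is_hd & ~is_border),
            "non_hd": med(~is_hd),
        },
        "mannwhitney_p_hd_vs_nonhd_unbiased_info": mw_p,
        "cell_types": {
            label: sum(1 for v in cell_types.values() if v == label)
            for label in ("pyramidal", "interneuron", "unclassified")
        },
        "state_preservation": comparisons,
        "config": asdict(cfg),
    }


def run_pipeline(session, config: Optional[PipelineConfig] = None,
                 out_dir=None) -> dict:
    """Run all stages on a Session (or a session directory path).

    Returns {"tuning": df, "info": df, "glm": df, "bias": df, "pairs": df,
    "summary": dict}; with ``out_dir`` set, also writes tuning.csv, info.csv,
    glm.csv, bias.csv, pairs.csv and summary.json (partial outputs are kept
    if a later stage fails).
    """
    cfg = config if config is not None else PipelineConfig()
    if not isinstance(session, Session):
        session = read_session(session)
    session.validate()
    if not session.spikes:
        raise PipelineStageError("tuning", ValueError("session has no cells"))
    wake = _wake_view(session, cfg)
    mask = speed_filter(session.trajectory, cfg.speed_threshold)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(name, df):
        if out is not None:
            df.to_csv(out / f"{name}.csv", index=False)

    results = {}
    tuning_df, curves = _run_tuning(session, wake, cfg)
    results["tuning"] = tuning_df
    emit("tuning", tuning_df)
    info_df = _run_information(session, wake, curves, cfg)
    results["info"] = info_df
    emit("info", info_df)
    glm_df = _run_glm(session, mask, curves, cfg)
    results["glm"] = glm_df
    emit("glm", glm_df)
    bias_df = _run_behavior(session, wake, cfg)
    results["bias"] = bias_df
    emit("bias", bias_df)
    pairs_df, comparisons = _run_statecorr(session, info_df, tuning_df, cfg)
    results["pairs"] = pairs_df
    emit("pairs", pairs_df)
    summary = _summary(session, tuning_df, info_df, glm_df, comparisons, cfg)
    results["summary"] = summary
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return results
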