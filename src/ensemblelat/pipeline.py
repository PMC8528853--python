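"""End-to-end orchestration: synth -> place fields -> assemblies -> ripples -> replay.

``run_pipeline`` runs every stage on a synthetic session, writes all output
tables as plain text and records a manifest (config, seeds, SHA-256 of every
output) so a rerun with the same seed reproduces every file byte-identically.
``group_report`` provides the routine group statistics (medians, means +- SEM,
two-sided rank-sum P, box-plot quantiles) used when comparing regimes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from . import assemblies as asm
from . import io as eio
from . import placefields as pf
from . import replay as rp
from . import ripples as rip
from .config import PipelineConfig
from .synth import generate_exploration, generate_rest
from .types import DecodingTemplate

__all__ = ["PipelineError", "run_pipeline", "group_report"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending entity."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_templates(place_units, position, cfg: PipelineConfig) -> Dict[int, DecodingTemplate]:
    templates = {}
    for d in (1, -1):
        rates, ids = [], []
        for u in place_units:
            m = pf.compute_ratemap(u, position, d, n_bins=cfg.n_spatial_bins,
                                   smoothing_sd_cm=cfg.smoothing_sd_cm,
                                   movement_velocity=cfg.movement_velocity)
            rates.append(m.rate_hz)
            ids.append(u.unit_id)
        m0 = pf.compute_ratemap(place_units[0], position, d, n_bins=cfg.n_spatial_bins,
                                smoothing_sd_cm=cfg.smoothing_sd_cm,
                                movement_velocity=cfg.movement_velocity)
        templates[d] = DecodingTemplate(unit_ids=np.array(ids), rates=np.array(rates),
                                        bin_centers=m0.bin_centers, direction=d,
                                        tau=cfg.tau)
    return templates


def run_pipeline(config: PipelineConfig, outdir, *, write_lfp: bool = False) -> dict:
    """Run every stage on a seeded synthetic session and serialize all tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- synth ------------------------------------------------------------
    try:
        config.synth.seed = config.synth.seed if config.synth.seed else config.seed
        pos_exp, units_exp, truth_exp = generate_exploration(config.synth)
        pos_rest, units_rest, lfp_l, lfp_r, truth_rest = generate_rest(config.synth)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage synth: {e}") from e
    eio.write_spikes(out / "spikes_exploration.tsv", units_exp)
    eio.write_spikes(out / "spikes_rest.tsv", units_rest)
    eio.write_position(out / "position_exploration.tsv", pos_exp)
    eio.write_position(out / "position_rest.tsv", pos_rest)
    eio.write_ground_truth(out / "ground_truth_exploration.json", truth_exp)
    eio.write_ground_truth(out / "ground_truth_rest.json", truth_rest)
    t_lfp = np.arange(lfp_l.size) / config.synth.lfp_fs
    if write_lfp:
        eio.write_lfp(out / "lfp_left.tsv", t_lfp, lfp_l)
        eio.write_lfp(out / "lfp_right.tsv", t_lfp, lfp_r)

    # --- place fields ------------------------------------------------------
    try:
        place_units = pf.filter_units(
            units_exp, pos_exp, min_total_spikes=config.min_total_spikes,
            min_movement_spikes=config.min_movement_spikes,
            max_isi_violation=config.max_isi_violation,
            isi_threshold_ms=config.isi_threshold_ms,
            movement_velocity=config.movement_velocity)
        if not place_units:
            raise ValueError("no units survive inclusion")
        rows = []
        for u in place_units:
            for d in (1, -1):
                m = pf.compute_ratemap(u, pos_exp, d, n_bins=config.n_spatial_bins,
                                       smoothing_sd_cm=config.smoothing_sd_cm,
                                       movement_velocity=config.movement_velocity)
                rows.append(dict(unit_id=u.unit_id, hemisphere=u.hemisphere, direction=d,
                                 si_bits_per_spike=pf.spatial_information(m),
                                 peak_rate_hz=float(m.rate_hz.max()),
                                 peak_position_cm=float(m.bin_centers[np.argmax(m.rate_hz)])))
        units_df = pd.DataFrame(rows)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage placefields: {e}") from e
    units_df.to_csv(out / "place_fields.tsv", sep="\t", index=False, float_format="%.6f")
    results["place_units"] = place_units
    results["place_fields"] = units_df

    # --- ripples -----------------------------------------------------------
    try:
        ripple_events = []
        for h, sig in (("L", lfp_l), ("R", lfp_r)):
            evs = rip.detect_ripples(sig, config.synth.lfp_fs, t_lfp, pos_rest,
                                     hemisphere=h, band=config.ripple_band,
                                     peak_sd=config.ripple_peak_sd,
                                     edge_sd=config.ripple_edge_sd,
                                     merge_ms=config.ripple_merge_ms,
                                     immobility_velocity=config.immobility_velocity)
            for e in evs:
                e.peak_freq_hz = rip.ripple_peak_frequency(
                    e, sig, config.synth.lfp_fs, t_lfp, band=config.ripple_band)[0]
            ripple_events.extend(evs)
        if not ripple_events:
            raise ValueError("no ripple events detected")
        left = [e for e in ripple_events if e.hemisphere == "L"]
        right = [e for e in ripple_events if e.hemisphere == "R"]
        xcorr = rip.bilateral_cross_correlogram(left, right) if left and right else None
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage ripples: {e}") from e
    eio.ripple_events_frame(ripple_events).to_csv(out / "ripples.tsv", sep="\t",
                                                  index=False, float_format="%.6f")
    if xcorr is not None:
        pd.DataFrame({"lag_ms": xcorr.lags_ms, "rate": xcorr.rate}).to_csv(
            out / "ripple_xcorr.tsv", sep="\t", index=False, float_format="%.6f")
    results["ripples"] = ripple_events
    results["xcorr"] = xcorr

    # --- assemblies ---------------------------------------------------------
    try:
        hemi = {u.unit_id: u.hemisphere for u in units_exp}
        asm_rows, patterns_all = [], []
        diag_all = {}
        rest_bin = asm.bin_and_zscore(units_rest, (0.0, pos_rest.times[-1]),
                                      bin_ms=config.assembly_bin_ms)
        rest_smooth = asm.smooth_zscores(rest_bin)
        for d in (1, -1):
            Z = asm.bin_and_zscore(place_units, (0.0, pos_exp.times[-1]),
                                   bin_ms=config.assembly_bin_ms,
                                   position=pos_exp, direction=d)
            patterns, diag = asm.detect_assembly_patterns(
                Z, seed=config.seed, n_restarts=config.ica_restarts)
            diag_all[f"direction_{d}"] = dict(
                eigenvalues=diag["eigenvalues"].tolist(),
                lambda_max=diag["lambda_max"], n_significant=diag["n_significant"],
                ica_seed=diag["ica_seed"], ica_restarts=diag["ica_restarts"])
            for p in patterns:
                p.laterality, p.dominant_side = asm.classify_laterality(p.members, hemi)
                track_Z = asm.smooth_zscores(Z)
                track_tr = asm.activation_strength(p, track_Z,
                                                   threshold=config.strength_threshold)
                missing = set(int(u) for u in p.unit_ids) - set(int(u) for u in rest_bin.unit_ids)
                if missing:
                    react = dict(rate_hz=float("nan"), strength=float("nan"),
                                 excluded=True)
                else:
                    rest_tr = asm.activation_strength(p, rest_smooth,
                                                      threshold=config.strength_threshold)
                    react = asm.reactivation_in_ripples(
                        rest_tr, ripple_events, min_rate=config.min_reactivation_rate)
                asm_rows.append(dict(
                    assembly_id=len(asm_rows), direction=d,
                    members=";".join(str(m) for m in sorted(p.members)),
                    laterality=p.laterality, dominant_side=p.dominant_side,
                    strength_track=float(np.mean(track_tr.peak_strengths))
                    if track_tr.peak_strengths.size else float("nan"),
                    strength_rest=react.get("strength", float("nan")),
                    reactivation_rate=react.get("rate_hz", float("nan")),
                    excluded=bool(react.get("excluded", False))))
                patterns_all.append(p)
        member_sets = [p.members for p in patterns_all if p.members]
        null_report = None
        if member_sets:
            null_report = asm.unilateral_fraction_null(
                member_sets, hemi, n_shuffles=config.n_shuffles, seed=config.seed)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage assemblies: {e}") from e
    pd.DataFrame(asm_rows).to_csv(out / "assemblies.tsv", sep="\t", index=False,
                                  float_format="%.6f")
    (out / "assembly_diagnostics.json").write_text(json.dumps(diag_all, indent=1))
    results["assemblies"] = patterns_all
    results["unilateral_null"] = null_report

    # --- replay -------------------------------------------------------------
    try:
        templates = _build_templates(place_units, pos_exp, config)
        place_ids = {u.unit_id for u in place_units}
        place_rest = [u for u in units_rest if u.unit_id in place_ids]
        candidates = rp.select_candidate_events(
            ripple_events, place_rest, min_cells=config.min_cells,
            min_ms=config.candidate_min_ms, max_ms=config.candidate_max_ms)
        replay_events = []
        for k, cand in enumerate(candidates):
            replay_events.append(rp.score_candidate(
                cand, place_rest, templates, n_shuffles=config.n_shuffles,
                seed=config.seed, alpha=config.alpha, event_id=k, compute_pcc=True))
        replay_df = pd.DataFrame([
            dict(event_id=e.event_id, ripple_hemisphere=e.ripple_hemisphere,
                 direction=e.direction, r=e.r, rz=e.rz, p_mc=e.p_mc,
                 significant=e.significant, distance_cm=e.distance_cm,
                 speed_m_s=e.speed_m_s, mean_jump_cm=e.mean_jump_cm,
                 n_participants=e.n_participants)
            for e in replay_events])
        pcc_acc: dict = {}
        for e in replay_events:
            if e.pcc:
                for uid, val in e.pcc.items():
                    pcc_acc.setdefault(uid, []).append(val)
        pcc_df = pd.DataFrame([
            dict(unit_id=uid, hemisphere=hemi[uid], mean_pcc=float(np.mean(v)),
                 n_events=len(v)) for uid, v in sorted(pcc_acc.items())])
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage replay: {e}") from e
    replay_df.to_csv(out / "replay.tsv", sep="\t", index=False, float_format="%.6f")
    pcc_df.to_csv(out / "pcc.tsv", sep="\t", index=False, float_format="%.6f")
    results["replay"] = replay_events
    results["replay_table"] = replay_df
    results["pcc_table"] = pcc_df

    # --- manifest -----------------------------------------------------------
    files = sorted(p for p in out.iterdir() if p.suffix in (".tsv", ".json")
                   and p.name != "manifest.json")
    manifest = dict(seed=config.seed, config=config.to_dict(),
                    non_default_parameters=config.non_default(),
                    outputs={p.name: _sha256(p) for p in files})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def group_report(df: pd.DataFrame, group_col: str, value_cols=None) -> dict:
    """Routine group statistics: medians, means +- SEM, rank-sum P, box quantiles."""
    if value_cols is None:
        value_cols = [c for c in df.columns
                      if c != group_col and np.issubdtype(df[c].dtype, np.number)]
    groups = list(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    report: dict = {}
    for col in value_cols:
        entry: dict = {"groups": {}}
        samples = {}
        for g in groups:
            v = df.loc[df[group_col] == g, col].dropna().to_numpy()
            if v.size < 2:
                entry["groups"][str(g)] = {"n": int(v.size), "skipped": True}
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            inliers = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
            entry["groups"][str(g)] = dict(
                n=int(v.size), median=float(med), mean=float(v.mean()),
                sem=float(v.std(ddof=1) / np.sqrt(v.size)),
                q1=float(q1), q3=float(q3),
                whisker_low=float(inliers.min()), whisker_high=float(inliers.max()))
            samples[g] = v
        if len(samples) >= 2:
            a, b = (samples[g] for g in list(samples)[:2])
            stat, p = ranksums(a, b)
            entry["ranksum_stat"], entry["ranksum_p"] = float(stat), float(p)
        report[col] = entry
    return report
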