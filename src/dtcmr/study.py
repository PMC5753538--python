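"""End-to-end synthetic study driver: a cohort of phantom "subjects" imaged
with both sequences at three cardiac phases, pushed through the full
preprocess -> fit -> maps -> quality pipeline, followed by the group
statistics and strain correlations.

Each subject gets its own nominal RR interval, peak strains and sheetlet
(E2A) configuration; E2A mobility (systole - diastole) is generated in
proportion to peak radial strain, emulating sheetlet reorientation as the
mechanism of wall thickening, so the strain correlation analysis has signal
to find. A cell (subject x sequence x phase) that fails any stage, or whose
HA-map score is 0, is marked failed and excluded from downstream statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom, preprocess, quality, strain as strain_mod, tensor_metrics
from .containers import AcquisitionProtocol, LVPhantomSpec

__all__ = ["ExperimentConfig", "run_study"]

PHASES = ("systole", "sweet_spot", "diastole")
SEQUENCES = ("STEAM", "M2SE")


@dataclass
class ExperimentConfig:
    """Study-level configuration (cohort, geometry per phase, noise)."""

    n_subjects: int = 15
    seed: int = 0
    grid_size: int = 64
    pixel_spacing_mm: float = 1.5
    noise_sigma: float = 0.05          # image units; S0 = 1 -> SNR ~ 20
    phases: tuple = PHASES
    # (endocardial, epicardial) radius in mm per phase: thick wall at systole
    phase_radii: dict = field(default_factory=lambda: {
        "systole": (10.0, 22.0),
        "sweet_spot": (12.0, 23.0),
        "diastole": (14.0, 24.0),
    })
    e2a_diastole_deg: float = 20.0
    e2a_mobility_per_strain: float = 80.0   # deg of E2A mobility per unit Err
    e2a_noise_deg: float = 3.0
    rr_mean_ms: float = 970.0
    rr_between_subject_sd_ms: float = 140.0
    rr_jitter_ms: float = 5.0
    peak_radial_strain_mean: float = 0.50
    peak_radial_strain_sd: float = 0.05
    peak_circ_strain_mean: float = -0.177
    peak_circ_strain_sd: float = 0.008
    n_shifted_frames: int = 2
    shift_px: tuple = (3.0, -2.0)
    # (sequence, phase) cells to corrupt heavily (most frames replaced by
    # noise, so rejection leaves too few for a tensor fit); emulates
    # motion-ruined acquisitions concentrating in specific conditions
    corrupt_cells: tuple = ()
    blood_threshold_factor: float = 2.0
    min_correlation: float = 0.80
    n_spokes: int = 72
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for ph in self.phases:
            if ph not in self.phase_radii:
                raise ValueError(f"no geometry for phase {ph!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _protocol(sequence: str, rr_ms: float, jitter_ms: float) -> AcquisitionProtocol:
    maker = (AcquisitionProtocol.steam if sequence == "STEAM"
             else AcquisitionProtocol.m2se)
    return maker(rr_nominal_ms=rr_ms, rr_jitter_ms=jitter_ms)


def _roi_mesocardium(truth) -> np.ndarray:
    """Small septal-like ROI: mid-wall pixels within a 60-degree sector."""
    spec = truth.spec
    n = spec.grid_size
    xs = (np.arange(n) - spec.centre[0])
    ys = (np.arange(n) - spec.centre[1])
    x, y = np.meshgrid(xs, ys)
    ang = np.degrees(np.arctan2(y, x))
    depth = np.nan_to_num(truth.coords.depth, nan=-1.0)
    return (truth.myocardium & (np.abs(ang) < 30.0)
            & (depth > 0.25) & (depth < 0.75))


def _run_cell(spec: LVPhantomSpec, protocol: AcquisitionProtocol,
              cfg: ExperimentConfig, seed: int, heavy_corruption: bool = False) -> dict:
    truth = phantom.build_tensor_field(spec)
    series = phantom.simulate_dwis(truth, protocol, seed=seed)
    if heavy_corruption:
        series = phantom.inject_artifacts(
            series, int(0.9 * series.n_frames), (0.0, 0.0), seed=seed + 1,
            replace_with_noise=True)
    elif cfg.n_shifted_frames:
        series = phantom.inject_artifacts(series, cfg.n_shifted_frames,
                                          cfg.shift_px, seed=seed + 1)
    nulled, ledger = preprocess.null_blood_pixels(
        series, cfg.blood_threshold_factor)
    registered, shifts = preprocess.register_frames(nulled)
    restored = preprocess.restore_blood_pixels(registered, ledger, shifts)
    cleaned, rejected = preprocess.reject_frames(restored,
                                                 cfg.min_correlation)
    corrected = preprocess.correct_b_values(cleaned, protocol.rr_nominal_ms,
                                            protocol.delta_ms)
    tensors = preprocess.fit_tensor_lls(corrected)
    maps = tensor_metrics.compute_scalar_maps(tensors, truth.coords)
    profiles = quality.extract_profiles(maps.ha, truth.coords,
                                        n_spokes=cfg.n_spokes)
    hag, ha_r2, ha_rmse = quality.hag_and_fit_stats(profiles)
    score, normal_frac = quality.score_ha_map(profiles)
    tastd = quality.ta_std(maps.ta, truth.myocardium)

    roi = _roi_mesocardium(truth)
    # repeated b_main frames along the first direction for the SNR estimate
    g0 = corrected.bvecs[-1]
    rep = [i for i in range(corrected.n_frames)
           if np.allclose(corrected.bvecs[i], g0)
           and corrected.bvals[i] > protocol.b_ref * 1.5]
    snr = np.nan
    if len(rep) >= 3 and spec.noise_sigma > 0 and roi.sum() >= 4:
        snr = quality.snr_repeated_measures(corrected.frames[rep], roi)
    mean_signal = float(corrected.frames[:, roi].mean()) if roi.any() else np.nan

    row = quality.summarize_lv(
        maps, truth.myocardium,
        hag=hag, ha_r2=ha_r2, ha_rmse=ha_rmse, ta_std=tastd,
        score=score, normal_fraction=normal_frac,
        snr=snr, mean_signal=mean_signal,
        n_rejected=len(rejected))
    row["failed"] = score == 0
    return row


def run_study(cfg: ExperimentConfig):
    """Run the full synthetic study.

    Returns ``(summary, report)``: a DataFrame with one row per
    subject x sequence x phase, and a dict of group statistics (sequence
    comparisons per phase, phase comparisons per sequence, strain
    correlations and the score-vs-RR correlation). Deterministic under a
    fixed seed. When ``cfg.out_dir`` is set the summary (CSV), the report
    (JSON) and the configuration + seed are written there.
    """
    t_start = time.time()
    root = np.random.SeedSequence(cfg.seed)
    subj_seeds = root.spawn(cfg.n_subjects)

    rows = []
    strain_rows = []
    for s_idx, ss in enumerate(subj_seeds):
        rng = np.random.default_rng(ss)
        rr = float(np.clip(rng.normal(cfg.rr_mean_ms,
                                      cfg.rr_between_subject_sd_ms),
                           600.0, 1400.0))
        peak_rad = float(rng.normal(cfg.peak_radial_strain_mean,
                                    cfg.peak_radial_strain_sd))
        peak_circ = float(rng.normal(cfg.peak_circ_strain_mean,
                                     cfg.peak_circ_strain_sd))
        e2a_dia = cfg.e2a_diastole_deg + float(rng.normal(0, cfg.e2a_noise_deg))
        mobility = (cfg.e2a_mobility_per_strain * peak_rad
                    + float(rng.normal(0, cfg.e2a_noise_deg)))
        e2a_by_phase = {
            "diastole": np.clip(e2a_dia, 1.0, 85.0),
            "systole": np.clip(e2a_dia + mobility, 1.0, 89.0),
            "sweet_spot": np.clip(e2a_dia + 0.5 * mobility, 1.0, 87.0),
        }
        cell_seed = int(rng.integers(0, 2 ** 31 - 1000))

        for sequence in SEQUENCES:
            protocol = _protocol(sequence, rr, cfg.rr_jitter_ms)
            for p_idx, ph in enumerate(cfg.phases):
                r_endo, r_epi = cfg.phase_radii[ph]
                spec = LVPhantomSpec(
                    grid_size=cfg.grid_size,
                    pixel_spacing_mm=cfg.pixel_spacing_mm,
                    centre=((cfg.grid_size - 1) / 2, (cfg.grid_size - 1) / 2),
                    r_endo_mm=r_endo, r_epi_mm=r_epi,
                    e2a_deg=float(e2a_by_phase[ph]),
                    noise_sigma=cfg.noise_sigma)
                meta = {"subject": s_idx, "sequence": sequence, "phase": ph,
                        "rr_nominal_ms": rr}
                try:
                    row = _run_cell(spec, protocol, cfg,
                                    seed=cell_seed + 10 * p_idx
                                    + (0 if sequence == "STEAM" else 5),
                                    heavy_corruption=(sequence, ph)
                                    in tuple(cfg.corrupt_cells))
                except Exception as exc:   # per-cell failure, cohort goes on
                    row = {"failed": True, "score": 0, "error": str(exc)}
                rows.append({**meta, **row})

        # strain is a per-subject measurement on the relaxed geometry
        r_endo, r_epi = cfg.phase_radii["diastole"]
        spec_dia = LVPhantomSpec(
            grid_size=cfg.grid_size, pixel_spacing_mm=cfg.pixel_spacing_mm,
            centre=((cfg.grid_size - 1) / 2, (cfg.grid_size - 1) / 2),
            r_endo_mm=r_endo, r_epi_mm=r_epi, e2a_deg=20.0)
        truth_dia = phantom.build_tensor_field(spec_dia)
        disp = phantom.simulate_displacements(spec_dia, peak_rad, peak_circ)
        curve = strain_mod.strain_from_displacements(disp, truth_dia.coords)
        strain_rows.append({"subject": s_idx,
                            "peak_radial": curve.peak_radial,
                            "peak_circumferential": curve.peak_circumferential})

    summary = pd.DataFrame(rows)
    strain_table = pd.DataFrame(strain_rows)
    report = _group_statistics(cfg, summary, strain_table)
    report["meta"] = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                      "n_subjects": cfg.n_subjects,
                      "elapsed_s": round(time.time() - t_start, 2)}

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        strain_table.to_csv(out / "strain.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    default=str))
        cfg_d = dataclasses.asdict(cfg)
        cfg_d["config_hash"] = cfg.config_hash()
        (out / "config.json").write_text(json.dumps(cfg_d, indent=1,
                                                    default=str))
    return summary, report


def _as_dict(res) -> dict:
    return dataclasses.asdict(res)


def _group_statistics(cfg: ExperimentConfig, summary: pd.DataFrame,
                      strain_table: pd.DataFrame) -> dict:
    ok = summary[~summary["failed"].astype(bool)].copy()
    report: dict = {"failures": int(summary["failed"].sum()),
                    "n_cells": len(summary)}

    seq_tests = {}
    for metric in ("md", "fa", "mode", "hag", "e2a_median"):
        per_phase = {}
        for ph in cfg.phases:
            try:
                per_phase[ph] = _as_dict(strain_mod.compare_sequences(
                    ok, metric, ph))
            except ValueError as exc:
                per_phase[ph] = {"error": str(exc)}
        seq_tests[metric] = per_phase
    report["sequence_comparisons"] = seq_tests

    phase_tests = {}
    for metric in ("md", "e2a_median"):
        per_seq = {}
        for seq in SEQUENCES:
            try:
                per_seq[seq] = [_as_dict(r) for r in
                                strain_mod.compare_phases(ok, metric, seq,
                                                          phases=tuple(cfg.phases))]
            except ValueError as exc:
                per_seq[seq] = {"error": str(exc)}
        phase_tests[metric] = per_seq
    report["phase_comparisons"] = phase_tests

    correlations = {}
    for seq in SEQUENCES:
        try:
            wide = ok[ok["sequence"] == seq].pivot_table(
                index="subject", columns="phase", values="e2a_median",
                aggfunc="first")
            if not {"systole", "diastole"}.issubset(wide.columns):
                raise ValueError(f"no successful systole+diastole pairs for {seq}")
            merged = wide.join(strain_table.set_index("subject"), how="inner")
            merged = merged.dropna(subset=["systole", "diastole", "peak_radial"])
            mobility = merged["systole"] - merged["diastole"]
            correlations[seq] = _as_dict(strain_mod.correlate_with_strain(
                mobility.values, merged["peak_radial"].values,
                label=f"e2a_mobility~peak_radial[{seq}]"))
        except ValueError as exc:
            correlations[seq] = {"error": str(exc)}
    report["strain_correlations"] = correlations

    try:
        sub = summary[summary["sequence"] == "M2SE"]
        sub = sub[sub["phase"] == "diastole"]
        report["score_rr_correlation"] = _as_dict(
            strain_mod.correlate_score_rr(sub["score"].values,
                                          sub["rr_nominal_ms"].values))
    except ValueError as exc:
        report["score_rr_correlation"] = {"error": str(exc)}
    return report
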