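"""End-to-end orchestration: simulate -> physio -> contrasts -> conditioning
-> lag maps -> thresholds -> summary statistics -> report.

The pipeline is deterministic under a fixed configuration: every stochastic
stage derives its seed from the configured seed, all seeds are echoed in
the report, and reruns produce byte-identical metric tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, conditioning, contrast, io, lagmap, physio, stats, surrogate, synth
from .errors import DataError
from .io import PipelineConfig

log = logging.getLogger("adcfmri")


def _condition(run, cfg: PipelineConfig):
    return conditioning.condition_run(
        run, cfg.smooth_fwhm_mm, cfg.highpass_cutoff_hz, cfg.highpass_order
    )


def analysis_runs(subject: synth.Subject, cfg: PipelineConfig) -> dict:
    """The four analysis series of one subject, conditioned and ready."""
    out = {}
    if "BOLD" in cfg.contrasts and "BOLD" in subject.runs:
        out["BOLD"] = _condition(subject.runs["BOLD"], cfg)
    if "dfMRI" in subject.runs:
        dfmri = subject.runs["dfMRI"]
        if "b200" in cfg.contrasts or "b1000" in cfg.contrasts:
            b200, b1000 = contrast.split_dfmri(dfmri)
            if "b200" in cfg.contrasts:
                out["b200"] = _condition(b200, cfg)
            if "b1000" in cfg.contrasts:
                out["b1000"] = _condition(b1000, cfg)
        if "ADC" in cfg.contrasts:
            adc = contrast.compute_adc_series(dfmri).as_run(dfmri)
            out["ADC"] = _condition(adc, cfg)
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: Path | str | None = None) -> dict:
    """Execute the full audit on the configured synthetic cohort.

    Writes intermediates and the report under ``out_dir`` and returns the
    report dictionary. QC-rejected runs are listed and excluded downstream;
    if QC rejects everything, the statistics stage is skipped with a
    message rather than failing.
    """
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = {
        "cohort": int(rng.integers(2**31)),
        "motion": int(rng.integers(2**31)),
        "surrogate": int(rng.integers(2**31)),
    }
    report: dict = {
        "version": __version__,
        "config_seed": cfg.seed,
        "seeds": seeds,
        "condition": cfg.condition,
        "stages": [],
    }

    # --- simulate ---------------------------------------------------------
    params = synth.CohortParams(
        n_subjects=cfg.n_subjects, grid=tuple(cfg.grid), condition=cfg.condition
    )
    cohort = synth.make_cohort(params, seed=seeds["cohort"])
    report["stages"].append("simulate")

    # --- QC ---------------------------------------------------------------
    motion_rng = np.random.default_rng(seeds["motion"])
    qc_records = {}
    accepted: list[synth.Subject] = []
    jitter = synth.jitter_for_mean_fd(cfg.motion_mean_fd_mm)
    for subj in cohort:
        n_vols = subj.runs[next(iter(subj.runs))].n_vols
        motion = synth.generate_motion(
            n_vols, jitter_mm=jitter, seed=int(motion_rng.integers(2**31))
        )
        io.save_motion(motion, out / f"{subj.subject_id}_motion.tsv")
        qc = conditioning.run_qc(
            motion,
            params.voxel_size_mm * cfg.qc_max_disp_voxels,
            mean_fd_limit_mm=cfg.qc_mean_fd_limit_mm,
        )
        qc_records[subj.subject_id] = qc.to_dict()
        if qc.accepted:
            accepted.append(subj)
        else:
            log.warning("QC rejected %s: %s", subj.subject_id, qc.reasons)
    report["qc"] = qc_records
    report["qc_rejected"] = [s for s, q in qc_records.items() if not q["accepted"]]
    report["stages"].append("qc")
    (out / "qc.json").write_text(json.dumps(qc_records, indent=1, sort_keys=True))

    if not accepted:
        report["stats"] = "skipped: all runs rejected by QC"
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        return report

    # --- physio -----------------------------------------------------------
    regressors = {}
    for subj in accepted:
        reg = physio.process_co2(
            subj.co2_trace,
            lowpass_cutoff_hz=cfg.lowpass_cutoff_hz,
            lowpass_order=cfg.lowpass_order,
            min_interval_s=cfg.peak_min_interval_s,
            outlier_mad_k=cfg.peak_outlier_mad_k,
            detrend_order=cfg.detrend_order,
        )
        regressors[subj.subject_id] = reg
        io.save_regressor(reg, out / f"{subj.subject_id}_petco2")
    report["stages"].append("physio")

    # --- contrasts + conditioning + lag maps -------------------------------
    lags = cfg.lags_s
    maps: dict = {}
    conditioned: dict = {}
    for subj in accepted:
        runs = analysis_runs(subj, cfg)
        conditioned[subj.subject_id] = runs
        maps[subj.subject_id] = {}
        for name, run in runs.items():
            xmap = lagmap.xcorr_map(
                run, regressors[subj.subject_id], mask=subj.masks["brain"],
                lags_s=lags, fixed_n=cfg.fixed_n,
            )
            xmap, shift = lagmap.normalize_latency(xmap, subj.masks["GM"])
            maps[subj.subject_id][name] = xmap
            io.write_nifti(xmap.zmax, out / f"{subj.subject_id}_{name}_zmax.nii.gz",
                           voxel_size_mm=params.voxel_size_mm)
            io.write_nifti(xmap.latency_s, out / f"{subj.subject_id}_{name}_latency.nii.gz",
                           voxel_size_mm=params.voxel_size_mm)
    report["stages"].append("xcorr")

    # --- thresholds ---------------------------------------------------------
    thresholds: dict = {}
    if cfg.condition == "breathhold":
        zthr = stats.breathhold_zthresh(cfg.breathhold_p)
        thresholds = {name: zthr for name in cfg.contrasts}
        report["threshold_rule"] = f"fixed z = {zthr:.4f} (p = {cfg.breathhold_p}, one-tailed)"
    else:
        for name in cfg.contrasts:
            pairs = [
                (regressors[s.subject_id], conditioned[s.subject_id][name])
                for s in accepted
                if name in conditioned[s.subject_id]
            ]
            if len(pairs) < 2:
                continue
            null = surrogate.build_null(
                pairs, n_surrogates=cfg.surrogate_n, n_voxels=cfg.surrogate_voxels,
                seed=seeds["surrogate"], lags_s=lags, contrast=name,
            )
            io.save_null(null, out / f"null_{name}")
            thresholds[name] = surrogate.significance_threshold(null, cfg.surrogate_p)
        report["threshold_rule"] = (
            f"surrogate empirical p < {cfg.surrogate_p} (one tail), "
            f"{cfg.surrogate_n} surrogates x {cfg.surrogate_voxels} voxels, leave-one-out"
        )
    report["thresholds"] = {k: float(v) for k, v in thresholds.items()}
    report["stages"].append("thresholds")

    # --- statistics ---------------------------------------------------------
    metrics = []
    for subj in accepted:
        for name, xmap in maps[subj.subject_id].items():
            try:
                metrics.append(
                    stats.summarize_run(
                        xmap, subj.masks["brain"], thresholds[name],
                        contrast=name, subject=subj.subject_id, run="run-01",
                    )
                )
            except DataError as exc:
                log.warning("metrics skipped for %s/%s: %s", subj.subject_id, name, exc)
    table = stats.metrics_table(metrics)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False)

    tests = {}
    for metric in ("pct_significant", "mean_r2_pct"):
        sub = table[table.metric == metric]
        groups = {c: sub[sub.contrast == c].value.to_list() for c in sub.contrast.unique()}
        df = stats.pairwise_tests(groups)
        df.to_csv(out / f"tests_{metric}.tsv", sep="\t", index=False)
        tests[metric] = df.to_dict(orient="records")
    report["pairwise_tests"] = tests
    report["median_pct_significant"] = {
        c: float(np.median(table[(table.metric == "pct_significant") & (table.contrast == c)].value))
        for c in table.contrast.unique()
    }
    report["stages"].append("stats")

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
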