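"""End-to-end orchestration: simulate/load -> events -> indexes -> compare."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrunkGaitError
from .gait_events import detect_events, temporal_parameters
from .group_stats import build_longitudinal_report, build_t0_report
from .harmonics import walk_hr
from .io_config import (
    AccelTrace,
    RunConfig,
    SubjectRecord,
    read_accel_csv,
    read_cohort_manifest,
    write_results_table,
)
from .smoothness_symmetry import walk_smoothness_symmetry
from .stability import walk_slle
from .synthetic_gait import COHORT_PRESETS, generate_cohort, write_cohort

logger = logging.getLogger("trunkgait")

T0_INDEX_COLUMNS = (
    "gait_speed", "hr_v", "hr_ml", "hr_ap", "slle_v", "slle_ml", "slle_ap",
    "ldlj_v", "ldlj_ml", "ldlj_ap", "si_stance", "si_swing", "si_double", "si_single",
)
LONGITUDINAL_COLUMNS = ("hr_v", "hr_ml", "hr_ap", "slle_v", "slle_ml", "gait_speed")


def compute_walk_indexes(
    trace: AccelTrace,
    record: SubjectRecord,
    config: RunConfig | None = None,
    slle_axes: tuple[str, ...] = ("AP", "ML", "V"),
) -> dict:
    """All gait indexes of one walk as a flat result row."""
    config = config or RunConfig(fs=trace.fs)
    events = detect_events(trace, config)
    temporal = temporal_parameters(events, trace.walk_distance, config.speed_mode)
    hr = walk_hr(trace, events, config)
    lambdas, embeddings = walk_slle(trace, events, config, axes=slle_axes)
    smooth = walk_smoothness_symmetry(trace, events, temporal,
                                      record.paretic_side, config)
    row = {
        "subject_id": record.subject_id,
        "group": record.group,
        "timepoint": record.timepoint,
        "nlr": record.nlr,
        "n_strides_detected": events.n_detected_strides,
        "n_strides_retained": len(events.stride_windows),
        "gait_speed": temporal.gait_speed,
        "stride_time": temporal.stride_time,
        "hr_v": hr.mean["V"], "hr_ml": hr.mean["ML"], "hr_ap": hr.mean["AP"],
        "hr_v_sd": hr.sd["V"], "hr_ml_sd": hr.sd["ML"], "hr_ap_sd": hr.sd["AP"],
    }
    for ax in slle_axes:
        row[f"slle_{ax.lower()}"] = lambdas[ax]
        row[f"slle_tau_{ax.lower()}"] = embeddings[ax].tau
        row[f"slle_m_{ax.lower()}"] = embeddings[ax].m
    row.update(smooth)
    row["warnings"] = "; ".join(events.warnings)
    return row


def analyze_cohort(
    traces: dict[tuple[str, str], AccelTrace],
    records: list[SubjectRecord],
    config: RunConfig | None = None,
    slle_axes: tuple[str, ...] = ("AP", "ML", "V"),
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the index chain over a cohort; failing walks are excluded, not fatal.

    Returns ``(index_table, exclusions)``.
    """
    rows, exclusions = [], []
    for rec in records:
        key = (rec.subject_id, rec.timepoint)
        if key not in traces:
            exclusions.append({"subject_id": rec.subject_id, "timepoint": rec.timepoint,
                               "reason": "trace missing"})
            continue
        try:
            rows.append(compute_walk_indexes(traces[key], rec, config, slle_axes))
        except TrunkGaitError as exc:
            logger.warning("excluding %s/%s: %s", rec.subject_id, rec.timepoint, exc)
            exclusions.append({"subject_id": rec.subject_id, "timepoint": rec.timepoint,
                               "reason": str(exc)})
    return pd.DataFrame(rows), exclusions


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    out_dir: str | Path,
    config: RunConfig | None = None,
    preset: str | None = "stroke-cohort",
    cohort_sizes: tuple[int, int, int] = (42, 32, 14),
    trace_dir: str | Path | None = None,
    seed: int = 0,
    timepoints: tuple[str, ...] = ("T0",),
    write_traces: bool = False,
) -> dict:
    """Full reproducible run; returns the run manifest (also written as JSON).

    Either a synthetic preset (default, the published-cohort analogue) or a
    directory of trace CSVs plus a manifest drives the run.  The manifest
    accounts for every walk: analyzed + excluded = input.
    """
    config = config or RunConfig(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if trace_dir is not None:
        records = read_cohort_manifest(Path(trace_dir) / "manifest.csv")
        traces = {}
        for rec in records:
            if rec.trace_path is None:
                continue
            traces[(rec.subject_id, rec.timepoint)] = read_accel_csv(
                Path(trace_dir) / rec.trace_path, fs=config.fs,
                subject_id=rec.subject_id, timepoint=rec.timepoint, config=config)
    else:
        if preset != "stroke-cohort":
            raise ValueError(f"unknown preset {preset!r}")
        cohort = generate_cohort(*cohort_sizes, presets=COHORT_PRESETS,
                                 seed=seed, timepoints=timepoints)
        records, traces = cohort.records, cohort.traces
        cohort.truth_table.to_csv(out / "truth.csv", index=False)
        if write_traces:
            write_cohort(cohort, out / "traces")

    indexes, exclusions = analyze_cohort(traces, records, config)
    if indexes.empty:
        raise TrunkGaitError("all walks failed the stride rule; nothing to analyze")
    write_results_table(indexes, out / "indexes.csv", config, seed)

    reports = {}
    t0 = indexes[indexes["timepoint"] == "T0"]
    if len(t0):
        t0_report = build_t0_report(t0, index_cols=T0_INDEX_COLUMNS)
        write_results_table(t0_report, out / "report_t0.csv", config, seed)
        reports["t0"] = "report_t0.csv"
    if indexes["timepoint"].nunique() > 1:
        patients = indexes[indexes["group"].isin(["IC", "SII"])]
        longi = build_longitudinal_report(patients, index_cols=LONGITUDINAL_COLUMNS)
        write_results_table(longi, out / "report_longitudinal.csv", config, seed)
        reports["longitudinal"] = "report_longitudinal.csv"

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "n_input": len(records),
        "n_analyzed": int(len(indexes)),
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
        "outputs": {
            name: _file_hash(out / name)
            for name in ["indexes.csv", *reports.values()]
        },
        "quality_flags": {
            row["subject_id"] + "/" + row["timepoint"]: row["warnings"]
            for _, row in indexes.iterrows() if row["warnings"]
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
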