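"""Reproducible simulate -> detect -> segment -> statistics pipelines.

Two analysis paths mirror the two experimental readouts:

* :func:`run_traces` — the whole-nucleolus/nucleoplasm intensity path:
  simulate per-cell compartment intensities, pool them into time courses,
  and compute CV, periodogram, dominant period with uncertainty band, the
  nucleolus-nucleoplasm correlation, and the 15->30 min fold change.
* :func:`run_images` — the per-unit path: render stacks per fixation time
  point, detect and quantify FC/DFC units, segment regions, then compute
  unit-intensity statistics (fold change, counts, Student's t) and the
  unit-level time-course statistics.

Every run writes its configuration, a summary JSON, per-stage CSVs and a
manifest (config hash, package version, file list, timestamps).  All
randomness flows from the single configured seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import check_seed
from .detect import DetectionParams, count_units, detect_units, records_to_frame
from .io import _as_plain, write_table
from .kinetics import KineticsConfig, NucleoplasmConfig, hela_config, lec_config
from .regions import measure_all_regions, nucleoplasm_mask, segment_nucleoli, segment_nucleus
from .scene import SceneConfig, simulate_timecourse_stacks
from .stats import (
    TimeCourse,
    assemble_timecourse,
    coefficient_of_variation,
    dominant_period,
    fold_change,
    pearson_correlation,
    period_interval,
    periodogram,
    students_t,
)
from .traces import simulate_traces

__all__ = ["PipelineConfig", "RunManifest", "preset_config", "run_traces", "run_images", "PRESETS"]

PRESETS = ("hela_sync", "lec_sync", "control", "cold")


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    preset: str = "hela_sync"
    seed: int = 0
    outdir: str = "results"
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    nucleoplasm: NucleoplasmConfig = field(default_factory=NucleoplasmConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    stacks_per_timepoint: int = 1
    cold: bool = False
    save_stacks: bool = False

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        self.seed = check_seed(self.seed)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_as_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def preset_config(preset: str, seed: int = 0, outdir: str = "results", **overrides) -> PipelineConfig:
    """Build a configuration for a named study condition.

    ``hela_sync`` — cold-released HeLa defaults; ``lec_sync`` — limbal
    epithelial cells (slower damping); ``control`` — untreated random-phase
    population; ``cold`` — cells still at +4 C (image amplitudes scaled by
    the residual cold factor).
    """
    if preset == "hela_sync":
        kin = hela_config()
    elif preset == "lec_sync":
        kin = lec_config()
    elif preset == "control":
        kin = hela_config(phase_mode="random")
    elif preset == "cold":
        kin = hela_config()
        overrides.setdefault("cold", True)
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    kin = overrides.pop("kinetics", kin)
    return PipelineConfig(preset=preset, seed=seed, outdir=outdir, kinetics=kin, **overrides)


@dataclass
class RunManifest:
    """Provenance record of one run."""

    config_hash: str
    version: str
    started: str
    finished: str
    files: list

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _write_summary(outdir: Path, summary: dict) -> Path:
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return path


def run_traces(config: PipelineConfig) -> dict:
    """Run the trace-based fluctuation analysis; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = _now()

    table = simulate_traces(config.kinetics, config.nucleoplasm, seed=config.seed)
    tc_nuc = assemble_timecourse(table, "nucleolar")
    tc_np = assemble_timecourse(table, "nucleoplasmic")
    pg = periodogram(tc_nuc)
    period = dominant_period(pg)
    low, high = period_interval(period, tc_nuc.interval)

    summary = {
        "preset": config.preset,
        "seed": config.seed,
        "cv_nucleolar": coefficient_of_variation(tc_nuc),
        "cv_nucleoplasmic": coefficient_of_variation(tc_np),
        "dominant_period_min": period,
        "period_interval_min": [low, high],
        "max_amplitude": float(pg.amplitudes.max()),
        "correlation_nucleolus_nucleoplasm": pearson_correlation(tc_nuc, tc_np),
        "fold_change_15_30": fold_change(tc_nuc, 15.0, 30.0)
        if 15.0 in tc_nuc.timepoints and 30.0 in tc_nuc.timepoints
        else None,
    }

    files = []
    for name, frame in (
        ("measurements.csv", table),
        ("timecourse_nucleolar.csv", tc_nuc.to_frame()),
        ("timecourse_nucleoplasmic.csv", tc_np.to_frame()),
        ("periodogram.csv", pg.to_frame()),
    ):
        write_table(outdir / name, frame)
        files.append(name)
    files.append(_write_summary(outdir, summary).name)
    RunManifest(config.config_hash(), __version__, started, _now(), sorted(files)).write(
        outdir / "manifest.json"
    )
    return summary


def run_images(config: PipelineConfig) -> dict:
    """Run the image-based per-unit analysis; returns the summary dict.

    Renders one or more stacks per fixation time point at the kinetics
    level (scaled by the cold factor for the ``cold`` preset), detects and
    quantifies units, segments regions, and aggregates unit intensities
    into per-time-point statistics.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = _now()

    samples = simulate_timecourse_stacks(
        config.kinetics,
        config.scene,
        seed=config.seed,
        stacks_per_timepoint=config.stacks_per_timepoint,
        cold=config.cold,
    )

    unit_frames = []
    region_rows = []
    per_tp: dict = {}
    files = []
    for idx, sample in enumerate(samples):
        records = detect_units(sample.stack, config.detection)
        frame = records_to_frame(records, config.detection)
        frame.insert(0, "stack", idx)
        frame.insert(0, "timepoint_min", sample.timepoint_min)
        unit_frames.append(frame)
        col = f"I_{config.detection.report_radius:.1f}"
        per_tp.setdefault(sample.timepoint_min, {"intensities": [], "counts": []})
        per_tp[sample.timepoint_min]["intensities"].extend(frame[col].tolist())
        per_tp[sample.timepoint_min]["counts"].append(
            count_units(records, config.detection.min_intensity, config.detection.report_radius)
        )

        nucleus = segment_nucleus(sample.stack)
        if not nucleus.is_empty:
            nucleoli = segment_nucleoli(sample.stack, nucleus)
            nplasm = nucleoplasm_mask(nucleus, nucleoli)
            for row in measure_all_regions(sample.stack, nucleus, nucleoli, nplasm):
                row.update(timepoint_min=sample.timepoint_min, stack=idx)
                region_rows.append(row)
        if config.save_stacks:
            from .io import write_stack

            name = f"stack_t{int(sample.timepoint_min):03d}_{idx:03d}.tif"
            write_stack(outdir / name, sample.stack)
            files.append(name)

    units = pd.concat(unit_frames, ignore_index=True)
    if units.empty:
        raise RuntimeError(
            "detection returned zero units at every time point; "
            "check scene/detection configuration (level, blur_sigma, min_peak_snr)"
        )

    tps = sorted(per_tp)
    mean_intensity = {t: float(np.mean(per_tp[t]["intensities"])) if per_tp[t]["intensities"] else 0.0 for t in tps}
    counts = {t: float(np.mean(per_tp[t]["counts"])) for t in tps}

    summary = {
        "preset": config.preset,
        "seed": config.seed,
        "mean_unit_intensity": {str(int(t)): mean_intensity[t] for t in tps},
        "mean_unit_count": {str(int(t)): counts[t] for t in tps},
    }
    if 15.0 in mean_intensity and 30.0 in mean_intensity and mean_intensity[15.0] > 0:
        summary["unit_intensity_fold_change_15_30"] = mean_intensity[30.0] / mean_intensity[15.0]
        a, b = per_tp[15.0]["intensities"], per_tp[30.0]["intensities"]
        if len(a) >= 2 and len(b) >= 2:
            t_stat, p = students_t(a, b)
            summary["students_t_15_vs_30"] = {"t": t_stat, "p": p}
        summary["unit_count_ratio_30_over_15"] = (
            counts[30.0] / counts[15.0] if counts[15.0] > 0 else None
        )

    # unit-level fluctuation statistics across the time course
    if len(tps) >= 3 and all(len(per_tp[t]["intensities"]) >= 2 for t in tps):
        arr_tp = np.asarray(tps, dtype=float)
        if np.allclose(np.diff(arr_tp), np.diff(arr_tp)[0]):
            means = np.array([mean_intensity[t] for t in tps])
            sems = np.array(
                [
                    np.std(per_tp[t]["intensities"], ddof=1)
                    / np.sqrt(len(per_tp[t]["intensities"]))
                    for t in tps
                ]
            )
            ns = np.array([len(per_tp[t]["intensities"]) for t in tps])
            tc = TimeCourse(arr_tp, means, sems, ns)
            pg = periodogram(tc)
            summary["cv_unit_intensity"] = coefficient_of_variation(tc)
            summary["dominant_period_min"] = dominant_period(pg)
            write_table(outdir / "timecourse_units.csv", tc.to_frame())
            write_table(outdir / "periodogram_units.csv", pg.to_frame())
            files += ["timecourse_units.csv", "periodogram_units.csv"]

    write_table(outdir / "units.csv", units)
    files.append("units.csv")
    if region_rows:
        write_table(outdir / "regions.csv", pd.DataFrame(region_rows))
        files.append("regions.csv")
    files.append(_write_summary(outdir, summary).name)
    RunManifest(config.config_hash(), __version__, started, _now(), sorted(files)).write(
        outdir / "manifest.json"
    )
    return summary
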