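"""End-to-end orchestration: recordings in, vital-sign report out.

``process_participant`` pools baseline-corrected epochs over a
participant's runs (typically 3) into per-condition averages and
measures the three components; ``run_pipeline`` adds normative scoring
and writes all artifacts to disk; ``cohort_report`` compares measure or
EBS distributions between groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nv_io
from .core import EEGRecording, ERPWaveform
from .detect import (ComponentMeasure, ComponentSpec, DEFAULT_SPECS,
                     extract_all, measures_to_values)
from .normative import load_normative
from .preprocess import average_conditions, preprocess_run
from .scoring import BVSReport, compare_groups, total_bvs


@dataclass
class RunConfig:
    """Configuration of a full scoring run."""

    recording_paths: list[str] = field(default_factory=list)
    event_paths: list[str] = field(default_factory=list)
    normative_path: str = ""
    out_dir: str = "."
    band_hz: tuple[float, float] = (1.0, 20.0)
    notch_hz: float | None = 60.0
    reject_threshold_uv: float = 100.0
    component_specs: dict[str, ComponentSpec] = field(default_factory=lambda: dict(DEFAULT_SPECS))
    participant: str = "participant"
    seed: int = 0

    def validate(self) -> None:
        if not self.recording_paths:
            raise ValueError("no recordings configured")
        if self.event_paths and len(self.event_paths) != len(self.recording_paths):
            raise ValueError("event_paths must match recording_paths one-to-one")
        for p in list(self.recording_paths) + list(self.event_paths) + (
            [self.normative_path] if self.normative_path else []
        ):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


def load_recording(path: str | Path, events_path: str | Path | None = None) -> EEGRecording:
    """Dispatch on extension: .edf via mne, anything else as CSV."""
    if str(path).lower().endswith(".edf"):
        return nv_io.read_edf(path, events_path)
    return nv_io.read_recording_csv(path, events_path)


def process_participant(
    recordings: list[EEGRecording],
    specs: dict[str, ComponentSpec] | None = None,
    band_hz=(1.0, 20.0),
    notch_hz: float | None = 60.0,
    reject_threshold_uv: float = 100.0,
) -> tuple[dict[str, ERPWaveform], dict[str, ComponentMeasure], dict]:
    """Pool epochs across runs, average per condition, measure components.

    Returns (averages per condition, component measures, processing log).
    """
    all_epochs = []
    logs = []
    for rec in recordings:
        epochs, log = preprocess_run(
            rec, band=band_hz, notch=notch_hz, reject_threshold=reject_threshold_uv
        )
        all_epochs.extend(epochs)
        logs.append(log)
    averages = average_conditions(all_epochs)
    measures = extract_all(averages, specs)
    return averages, measures, {"runs": logs, "n_runs": len(recordings)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute preprocess -> average -> detect -> score and write artifacts.

    Writes per-condition waveform CSVs, a measures CSV, a report JSON and
    a processing log under ``config.out_dir``. The returned dict carries
    ``status`` ("ok" or "components_absent"), the measures and the
    report.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    recordings = [
        load_recording(p, e)
        for p, e in zip(
            config.recording_paths,
            config.event_paths or [None] * len(config.recording_paths),
        )
    ]
    averages, measures, log = process_participant(
        recordings,
        specs=config.component_specs,
        band_hz=config.band_hz,
        notch_hz=config.notch_hz,
        reject_threshold_uv=config.reject_threshold_uv,
    )

    for cond, wave in averages.items():
        nv_io.write_waveform_csv(wave, out_dir / f"{config.participant}_{cond}.csv")
    measure_rows = [
        {
            "participant": config.participant,
            "run": "pooled",
            "component": m.name,
            "channel": m.channel,
            "amplitude_uV": m.amplitude,
            "latency_ms": m.latency,
            "found": m.found,
        }
        for m in measures.values()
    ]
    nv_io.write_measures_csv(measure_rows, out_dir / f"{config.participant}_measures.csv")

    missing = [name for name, m in measures.items() if not m.found]
    report: BVSReport | None = None
    if not missing and config.normative_path:
        db = load_normative(config.normative_path)
        report = total_bvs(measures_to_values(measures), db)

    status = "ok" if not missing else "components_absent"
    log_payload = {
        "participant": config.participant,
        "seed": config.seed,
        "status": status,
        "missing_components": missing,
        "processing": log,
        "config": {
            "band_hz": list(config.band_hz),
            "notch_hz": config.notch_hz,
            "reject_threshold_uv": config.reject_threshold_uv,
            "recordings": list(config.recording_paths),
            "normative": config.normative_path,
        },
    }
    (out_dir / f"{config.participant}_log.json").write_text(json.dumps(log_payload, indent=2))
    result = {
        "status": status,
        "measures": measure_rows,
        "report": report.to_dict() if report is not None else None,
    }
    (out_dir / f"{config.participant}_report.json").write_text(json.dumps(result, indent=2))
    return result


def cohort_report(measures: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Group comparison table over a long-format measure frame.

    ``measures`` needs columns ``participant, group, measure_id`` and
    ``value_col``. For each measure the table reports per-group mean and
    SD plus the gated two-group test (t-test or rank-sum). With a single
    group the comparison is skipped with a warning.
    """
    required = {"participant", "group", "measure_id", value_col}
    if not required.issubset(measures.columns):
        raise ValueError(f"measure frame must have columns {sorted(required)}")
    groups = sorted(measures["group"].unique())
    rows = []
    for mid, sub in measures.groupby("measure_id"):
        row: dict = {"measure_id": mid}
        for g in groups:
            vals = sub.loc[sub["group"] == g, value_col].to_numpy()
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"{g}_n"] = vals.size
        if len(groups) >= 2:
            a = sub.loc[sub["group"] == groups[0], value_col].to_numpy()
            b = sub.loc[sub["group"] == groups[1], value_col].to_numpy()
            stat, p, test = compare_groups(a, b)
            row.update({"statistic": stat, "p": p, "test": test})
        rows.append(row)
    if len(groups) < 2:
        warnings.warn("single group: comparison skipped")
    return pd.DataFrame(rows)
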