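"""File I/O: recordings (CSV + JSON sidecar, or EDF in), event tables,
averaged waveforms, measures, and processing logs.

The native on-disk recording format is plain text: a CSV with a
``time_s`` column plus one column per channel (microvolts) and a JSON
sidecar carrying sampling rate, channel order and provenance metadata.
EDF input is supported through mne when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEGRecording, ERPWaveform

EVENT_COLUMNS = ["sample_index", "code", "condition", "cycle_index"]


def write_event_csv(events: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_event_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    return events[EVENT_COLUMNS]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording_csv(rec: EEGRecording, path: str | Path, events_path: str | Path | None = None) -> None:
    """Write a recording as CSV + JSON sidecar (and optionally its events)."""
    path = Path(path)
    frame = pd.DataFrame({"time_s": np.arange(rec.n_samples) / rec.fs})
    for i, ch in enumerate(rec.channels):
        frame[ch] = rec.data[i]
    frame.to_csv(path, index=False, float_format="%.6f")
    meta = {"fs": rec.fs, "channels": rec.channels, **rec.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str))
    if events_path is not None and rec.events is not None:
        write_event_csv(rec.events, events_path)


def read_recording_csv(path: str | Path, events_path: str | Path | None = None) -> EEGRecording:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta.pop("fs"))
        channels = meta.pop("channels")
    else:
        dt = np.diff(frame["time_s"].to_numpy()[:2])[0]
        fs = 1.0 / dt
        channels = [c for c in frame.columns if c != "time_s"]
        meta = {}
    data = np.stack([frame[c].to_numpy() for c in channels])
    events = read_event_csv(events_path) if events_path else None
    return EEGRecording(data=data, channels=list(channels), fs=fs, events=events, meta=meta)


def read_edf(path: str | Path, events_path: str | Path | None = None) -> EEGRecording:
    """Read an EDF recording (requires the optional mne dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF input requires mne: pip install neurovitals[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = read_event_csv(events_path) if events_path else None
    return EEGRecording(
        data=data,
        channels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        events=events,
        meta={"source": str(path), "format": "edf"},
    )


def write_waveform_csv(wave: ERPWaveform, path: str | Path) -> None:
    """Averaged waveform as CSV (time_ms + channel columns) + sidecar."""
    path = Path(path)
    wave.to_frame().to_csv(path, index=False, float_format="%.6f")
    _sidecar(path).write_text(json.dumps({
        "condition": wave.condition,
        "n_accepted": wave.n_accepted,
        "n_rejected": wave.n_rejected,
        "channels": wave.channels,
    }, indent=2))


def read_waveform_csv(path: str | Path) -> ERPWaveform:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    channels = meta.get("channels", [c for c in frame.columns if c != "time_ms"])
    return ERPWaveform(
        condition=meta.get("condition", "unknown"),
        data=np.stack([frame[c].to_numpy() for c in channels]),
        channels=list(channels),
        times_ms=frame["time_ms"].to_numpy(),
        n_accepted=int(meta.get("n_accepted", 0)),
        n_rejected=int(meta.get("n_rejected", 0)),
    )


def write_measures_csv(rows: list[dict], path: str | Path) -> None:
    """Component measures table: participant, run, component, channel,
    amplitude_uV, latency_ms, found."""
    cols = ["participant", "run", "component", "channel", "amplitude_uV", "latency_ms", "found"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def read_measures_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
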