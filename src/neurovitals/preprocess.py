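"""Raw EEG to conditional trial averages.

Chain: zero-phase spectral filtering (1-20 Hz bandpass, 60 Hz notch) ->
ocular regression against the EOG channels -> segmentation into
-100..900 ms epochs (tones lock to tone onset, word pairs lock to the
target word, where the semantic violation is realized) -> baseline
correction over [-100, 0) ms -> amplitude-threshold artifact rejection
-> conditional averaging over accepted epochs.

All filters are applied forward-backward so embedded component latencies
are not shifted. Sample indexing is 0-based; the epoch window is closed
at both ends (-100..900 ms -> 501 samples at 500 Hz).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .core import EEGRecording, Epoch, ERPWaveform

DEFAULT_BAND = (1.0, 20.0)
DEFAULT_NOTCH = 60.0
DEFAULT_WINDOW_MS = (-100.0, 900.0)
DEFAULT_REJECT_UV = 100.0


class EmptyAverageError(ValueError):
    """No accepted epochs available for the requested condition."""


def filter_recording(
    rec: EEGRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    notch: float | None = DEFAULT_NOTCH,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase bandpass + notch on every channel.

    4th-order Butterworth bandpass and a 2nd-order IIR notch, both run
    forward-backward (`sosfiltfilt`/`filtfilt`), which squares the
    magnitude response and cancels phase: embedded peaks do not move.
    The 1 Hz high-pass edge removes DC.
    """
    lo, hi = band
    nyq = rec.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) or inverted")
    out = rec.copy()
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    if notch is not None:
        if notch >= nyq:
            raise ValueError("notch frequency above Nyquist")
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out.data = signal.filtfilt(b, a, out.data, axis=1)
    out.meta.setdefault("filters", []).append(
        {"band_hz": list(band), "notch_hz": notch, "order": 4, "zero_phase": True}
    )
    return out


def ocular_correct(rec: EEGRecording) -> EEGRecording:
    """Regress EOG out of the scalp channels (least squares).

    Each scalp channel is replaced by its residual after projecting onto
    the EOG channels; EOG channels pass through unchanged. Works on
    high-passed data (zero-mean), so no intercept term is needed. If no
    EOG channel is present the recording is returned unmodified with a
    warning flag in ``meta``.
    """
    eog = rec.eog_channels
    out = rec.copy()
    if not eog:
        warnings.warn("no EOG channels: ocular correction skipped")
        out.meta["ocular_correction"] = "skipped_no_eog"
        return out
    X = np.stack([rec.get(c) for c in eog], axis=1)  # (n_samples, n_eog)
    coeffs = {}
    for ch in rec.scalp_channels:
        y = rec.get(ch)
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        out.data[out.channel_index(ch)] = y - X @ b
        coeffs[ch] = b.tolist()
    out.meta["ocular_correction"] = {"eog_channels": eog, "coefficients": coeffs}
    return out


def _epoch_grid(fs: float, window_ms: tuple[float, float]) -> tuple[int, int, np.ndarray]:
    pre = int(round(-window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    times_ms = np.arange(-pre, post + 1) * 1000.0 / fs
    return pre, post, times_ms


def segment(
    rec: EEGRecording,
    events: pd.DataFrame | None = None,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> tuple[list[Epoch], int]:
    """Cut stimulus-locked epochs.

    Tone events epoch on the tone onset; word pairs epoch on the target
    word only (primes are not epoched). Returns the epochs plus the count
    of events dropped because their window fell outside the recording.
    """
    ev = events if events is not None else rec.events
    if ev is None:
        raise ValueError("no event table available")
    pre, post, times_ms = _epoch_grid(rec.fs, window_ms)
    epochs: list[Epoch] = []
    n_dropped = 0
    for idx, row in ev.iterrows():
        code = row["code"]
        if code == "prime_word":
            continue
        s = int(row["sample_index"])
        start, stop = s - pre, s + post + 1
        if start < 0 or stop > rec.n_samples:
            n_dropped += 1
            continue
        epochs.append(
            Epoch(
                condition=str(row["condition"]),
                data=rec.data[:, start:stop].copy(),
                channels=list(rec.channels),
                times_ms=times_ms,
                event_index=int(idx),
            )
        )
    return epochs, n_dropped


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract the per-channel mean of the pre-stimulus baseline.

    The baseline is the half-open interval [-100, 0) ms; correction is
    idempotent.
    """
    mask = epoch.times_ms < 0
    if not mask.any():
        raise ValueError("epoch window does not include a pre-stimulus baseline")
    epoch.data = epoch.data - epoch.data[:, mask].mean(axis=1, keepdims=True)
    return epoch


def reject_artifacts(
    epochs: list[Epoch],
    threshold: float = DEFAULT_REJECT_UV,
    scalp_only: bool = True,
) -> list[Epoch]:
    """Flag epochs whose absolute amplitude exceeds ``threshold`` uV.

    Only scalp channels are inspected by default (EOG legitimately
    carries large blink deflections). Flags are set in place; the list is
    returned for chaining.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    for ep in epochs:
        if scalp_only:
            rows = [ep.channels.index(c) for c in ep.channels if c in ("Fz", "Cz", "Pz")]
            dat = ep.data[rows]
        else:
            dat = ep.data
        peak = float(np.abs(dat).max())
        if peak > threshold:
            ep.rejected = True
            ep.reject_reason = f"amplitude {peak:.1f} uV > {threshold:g} uV"
    return epochs


def conditional_average(epochs: list[Epoch], condition: str) -> ERPWaveform:
    """Pointwise mean over accepted epochs of one condition."""
    selected = [e for e in epochs if e.condition == condition]
    accepted = [e for e in selected if not e.rejected]
    if not accepted:
        raise EmptyAverageError(f"no accepted epochs for condition {condition!r}")
    data = np.mean([e.data for e in accepted], axis=0)
    return ERPWaveform(
        condition=condition,
        data=data,
        channels=list(accepted[0].channels),
        times_ms=accepted[0].times_ms,
        n_accepted=len(accepted),
        n_rejected=len(selected) - len(accepted),
    )


def preprocess_run(
    rec: EEGRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    notch: float | None = DEFAULT_NOTCH,
    reject_threshold: float = DEFAULT_REJECT_UV,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> tuple[list[Epoch], dict]:
    """Full single-run chain up to accepted, baseline-corrected epochs.

    Returns the epochs and a processing log (filter settings, drop and
    rejection counts per condition).
    """
    filtered = filter_recording(rec, band=band, notch=notch)
    corrected = ocular_correct(filtered)
    epochs, n_dropped = segment(corrected, window_ms=window_ms)
    for ep in epochs:
        baseline_correct(ep)
    reject_artifacts(epochs, threshold=reject_threshold)
    conditions = sorted({e.condition for e in epochs})
    log = {
        "band_hz": list(band),
        "notch_hz": notch,
        "reject_threshold_uv": reject_threshold,
        "window_ms": list(window_ms),
        "n_events_dropped": n_dropped,
        "per_condition": {
            c: {
                "n_total": sum(e.condition == c for e in epochs),
                "n_rejected": sum(e.condition == c and e.rejected for e in epochs),
            }
            for c in conditions
        },
    }
    return epochs, log


def average_conditions(epochs: list[Epoch]) -> dict[str, ERPWaveform]:
    """Conditional averages for every condition present in ``epochs``."""
    out = {}
    for cond in sorted({e.condition for e in epochs}):
        try:
            out[cond] = conditional_average(epochs, cond)
        except EmptyAverageError:
            continue
    return out
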