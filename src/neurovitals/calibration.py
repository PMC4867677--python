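"""Hardware-calibration quality metrics for a known multi-sine input.

A ground-truth test signal (equal-amplitude 5, 10, 15 and 30 Hz
sinusoids) is played into the amplifier and re-recorded over repeated
sessions. Quality metrics:

* SNR — Welch spectral power summed in narrow bands around the four
  signal tones, divided by the power around 60 Hz (line noise);
* inter-channel stability — correlation between the two recording
  channels across samples;
* day-over-day stability — mean absolute percentage change in session
  peak-to-peak voltage from one session to the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

SIGNAL_FREQS = (5.0, 10.0, 15.0, 30.0)
NOISE_FREQ = 60.0
#: Half-width of the integration band around each tone, Hz.
BAND_HALF_WIDTH = 0.5
#: Welch segment length, seconds (0.25 Hz resolution).
WELCH_SEGMENT_S = 4.0
#: Reported when the 60 Hz band holds essentially no power.
SNR_CAP = 1e12


@dataclass
class CalibrationReport:
    snr: float
    interchannel_r: float | None = None
    day_over_day_change: float | None = None  # percent
    peak_to_peak: list[float] = field(default_factory=list)  # volts, per session

    def to_dict(self) -> dict:
        return {
            "snr": self.snr,
            "interchannel_r": self.interchannel_r,
            "day_over_day_change_percent": self.day_over_day_change,
            "peak_to_peak": self.peak_to_peak,
        }


def make_test_signal(duration: float = 300.0, fs: float = 500.0, amplitude: float = 1.0) -> np.ndarray:
    """Equal-amplitude sum of the four calibration tones."""
    if fs <= 2 * max(SIGNAL_FREQS):
        raise ValueError("sampling rate too low for a 30 Hz tone (need fs > 120 Hz directly; "
                         f"got {fs})")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    for f in SIGNAL_FREQS:
        out += amplitude * np.sin(2 * np.pi * f * t)
    return out


def _band_power(freqs: np.ndarray, psd: np.ndarray, center: float) -> float:
    mask = np.abs(freqs - center) <= BAND_HALF_WIDTH
    return float(np.trapezoid(psd[mask], freqs[mask]))


def calibration_snr(recorded: np.ndarray, fs: float) -> float:
    """Signal-to-noise power ratio of a recorded calibration waveform.

    Power integrates over +/-0.5 Hz around each signal tone and around
    60 Hz, from a Welch spectrum with 4 s Hann segments. A noise band
    with essentially zero power caps the ratio at ``SNR_CAP``.
    """
    x = np.asarray(recorded, dtype=float)
    if x.size / fs < 10.0:
        raise ValueError("need at least 10 s of recording for a stable spectrum")
    nperseg = int(round(WELCH_SEGMENT_S * fs))
    freqs, psd = sig.welch(x, fs=fs, nperseg=min(nperseg, x.size))
    signal_power = sum(_band_power(freqs, psd, f) for f in SIGNAL_FREQS)
    noise_power = _band_power(freqs, psd, NOISE_FREQ)
    total = signal_power + noise_power
    if total <= 0:
        return 0.0
    if noise_power <= total * 1e-15:
        return SNR_CAP
    return signal_power / noise_power


def peak_to_peak(waveform: np.ndarray) -> float:
    """Session peak-to-peak voltage, averaged over channels if 2-D."""
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    return float(np.mean(w.max(axis=1) - w.min(axis=1)))


def percent_change(session_peaks) -> float:
    """Mean absolute % change of consecutive session peak values."""
    peaks = np.asarray(session_peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("need >= 2 sessions")
    if np.any(peaks[:-1] == 0):
        raise ValueError("zero peak voltage; percentage change undefined")
    changes = np.abs(np.diff(peaks)) / peaks[:-1]
    return float(100.0 * changes.mean())


def stability_metrics(sessions: list[np.ndarray], fs: float = 500.0) -> CalibrationReport:
    """Stability report across repeated calibration sessions.

    Each session is a (2, n_samples) two-channel recording. SNR is
    reported for the first channel of the first session; inter-channel
    correlation is averaged over sessions.
    """
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    rs, peaks = [], []
    for s in sessions:
        s = np.asarray(s, dtype=float)
        if s.ndim != 2 or s.shape[0] != 2:
            raise ValueError("each session must be a (2, n_samples) array")
        rs.append(float(np.corrcoef(s[0], s[1])[0, 1]))
        peaks.append(peak_to_peak(s))
    return CalibrationReport(
        snr=calibration_snr(np.asarray(sessions[0])[0], fs),
        interchannel_r=float(np.mean(rs)),
        day_over_day_change=percent_change(peaks),
        peak_to_peak=peaks,
    )
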