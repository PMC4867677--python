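"""Core in-memory containers shared across the pipeline.

Voltages are microvolts throughout; time is seconds for raw recordings
and milliseconds for epoch/ERP grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Midline scalp montage used for ERP measurement.
SCALP_CHANNELS = ("Fz", "Cz", "Pz")
#: Vertical / horizontal electro-oculogram channels used for ocular regression.
EOG_CHANNELS = ("EOGv", "EOGh")
DEFAULT_CHANNELS = SCALP_CHANNELS + EOG_CHANNELS

#: Acquisition sampling rate in Hz.
DEFAULT_FS = 500.0


@dataclass
class EEGRecording:
    """Channel-labelled continuous EEG with an optional event table.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    channels
        Channel labels, one per row of ``data``.
    fs
        Sampling rate in Hz.
    events
        Event table with columns ``sample_index, code, condition,
        cycle_index`` (0-based sample indexing), or None.
    meta
        Free-form provenance (seed, simulation parameters, filters applied).
    """

    data: np.ndarray
    channels: list[str]
    fs: float = DEFAULT_FS
    events: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count does not match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError as exc:
            raise KeyError(f"channel {name!r} not in recording") from exc

    def get(self, name: str) -> np.ndarray:
        """Return one channel's samples (view, not copy)."""
        return self.data[self.channel_index(name)]

    @property
    def scalp_channels(self) -> list[str]:
        return [c for c in self.channels if c in SCALP_CHANNELS]

    @property
    def eog_channels(self) -> list[str]:
        return [c for c in self.channels if c in EOG_CHANNELS]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            channels=list(self.channels),
            fs=self.fs,
            events=None if self.events is None else self.events.copy(),
            meta=dict(self.meta),
        )


@dataclass
class Epoch:
    """One stimulus-locked segment on the −100..900 ms grid.

    ``data`` is ``(n_channels, n_times)``; ``times_ms`` is shared across
    epochs of a segmentation.
    """

    condition: str
    data: np.ndarray
    channels: list[str]
    times_ms: np.ndarray
    event_index: int
    rejected: bool = False
    reject_reason: str | None = None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass
class ERPWaveform:
    """Conditional trial average over accepted epochs."""

    condition: str
    data: np.ndarray
    channels: list[str]
    times_ms: np.ndarray
    n_accepted: int
    n_rejected: int = 0

    def get(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError as exc:
            raise KeyError(f"channel {name!r} not in average") from exc

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_ms": self.times_ms})
        for i, ch in enumerate(self.channels):
            out[ch] = self.data[i]
        return out
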