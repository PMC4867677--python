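"""Template-matching identification of N100, P300 and N400.

A component is identified as the most extreme sample of its expected
polarity inside its expected latency window, at its designated midline
channel. N100 and P300 are read from the deviant-tone average, N400 from
the incongruent-target average. Amplitude is the peak-to-peak measure:
the component extremum minus the preceding extremum of opposite
polarity, searched backward from the component peak to a per-component
bound. When no opposite-polarity deflection precedes the peak, the
measure falls back to peak minus the 0 uV baseline and is flagged.

Default windows (ms): N100 70-170, P300 250-500, N400 300-700 — wide
enough to cover the published group means plus three between-participant
SDs. Channels: N100 at Cz, P300 and N400 at Pz (classic midline maxima).
Ties between equal extrema resolve to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ERPWaveform

NEGATIVE, POSITIVE = "negative", "positive"


@dataclass(frozen=True)
class ComponentSpec:
    """Where and what to look for, for one ERP component."""

    name: str
    polarity: str  # "negative" | "positive"
    window_ms: tuple[float, float]
    condition: str  # source conditional average
    channel: str
    preceding_bound_ms: float  # backward search limit for the opposite peak

    def __post_init__(self):
        if self.polarity not in (NEGATIVE, POSITIVE):
            raise ValueError("polarity must be 'negative' or 'positive'")
        if (self.name.startswith("N") and self.polarity != NEGATIVE) or (
            self.name.startswith("P") and self.polarity != POSITIVE
        ):
            raise ValueError(f"polarity {self.polarity} inconsistent with name {self.name}")


DEFAULT_SPECS: dict[str, ComponentSpec] = {
    "N100": ComponentSpec("N100", NEGATIVE, (70.0, 170.0), "deviant", "Cz", 50.0),
    "P300": ComponentSpec("P300", POSITIVE, (250.0, 500.0), "deviant", "Pz", 70.0),
    "N400": ComponentSpec("N400", NEGATIVE, (300.0, 700.0), "incongruent", "Pz", 250.0),
}

#: The six scalar measures fed into the vital-sign framework.
MEASURE_IDS = (
    "N100_amplitude", "N100_latency",
    "P300_amplitude", "P300_latency",
    "N400_amplitude", "N400_latency",
)


@dataclass
class ComponentMeasure:
    """Signed peak-to-peak amplitude (uV) and latency (ms) of one component."""

    name: str
    found: bool
    latency: float | None = None
    amplitude: float | None = None
    peak_value: float | None = None
    preceding_peak_latency: float | None = None
    preceding_peak_value: float | None = None
    baseline_fallback: bool = False
    channel: str | None = None
    condition: str | None = None


def find_extremum(
    waveform: ERPWaveform,
    polarity: str,
    window_ms: tuple[float, float],
    channel: str,
) -> tuple[float, float] | None:
    """Most extreme correctly-signed sample in the window.

    Returns (latency_ms, value_uV) or None when no sample of the required
    sign exists in the window. Equal extrema resolve to the earliest.
    """
    lo, hi = window_ms
    t = waveform.times_ms
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} outside waveform span")
    y = waveform.get(channel)[mask]
    tt = t[mask]
    if polarity == NEGATIVE:
        i = int(np.argmin(y))  # argmin returns the first of equal minima
        if y[i] >= 0:
            return None
    else:
        i = int(np.argmax(y))
        if y[i] <= 0:
            return None
    return float(tt[i]), float(y[i])


def measure_component(waveform: ERPWaveform, spec: ComponentSpec) -> ComponentMeasure:
    """Peak-to-peak measurement of one component.

    amplitude = value(component extremum) - value(preceding
    opposite-polarity extremum); the preceding extremum is searched from
    the component peak backward to ``spec.preceding_bound_ms``. A
    monotone rise with no preceding opposite deflection falls back to the
    0 uV baseline and is flagged.
    """
    hit = find_extremum(waveform, spec.polarity, spec.window_ms, spec.channel)
    if hit is None:
        return ComponentMeasure(name=spec.name, found=False, channel=spec.channel,
                                condition=waveform.condition)
    peak_lat, peak_val = hit
    opposite = POSITIVE if spec.polarity == NEGATIVE else NEGATIVE
    measure = ComponentMeasure(
        name=spec.name, found=True, latency=peak_lat, peak_value=peak_val,
        channel=spec.channel, condition=waveform.condition,
    )
    pre_window = (spec.preceding_bound_ms, peak_lat)
    prev = None
    if pre_window[0] < pre_window[1]:
        # half-open on the right: the component peak itself is excluded
        t = waveform.times_ms
        mask = (t >= pre_window[0]) & (t < pre_window[1])
        if mask.any():
            sub = ERPWaveform(
                condition=waveform.condition,
                data=waveform.data[:, mask],
                channels=list(waveform.channels),
                times_ms=t[mask],
                n_accepted=waveform.n_accepted,
            )
            prev = find_extremum(sub, opposite, (float(t[mask][0]), float(t[mask][-1])), spec.channel)
    if prev is None:
        measure.amplitude = peak_val  # relative to 0 uV baseline
        measure.baseline_fallback = True
    else:
        measure.preceding_peak_latency, measure.preceding_peak_value = prev
        measure.amplitude = peak_val - prev[1]
    return measure


def extract_all(
    averages: dict[str, ERPWaveform],
    specs: dict[str, ComponentSpec] | None = None,
) -> dict[str, ComponentMeasure]:
    """Measure all three components from their source conditional averages.

    ``averages`` maps condition name -> ERPWaveform and must contain the
    deviant-tone and incongruent-target averages.
    """
    specs = specs or DEFAULT_SPECS
    out: dict[str, ComponentMeasure] = {}
    for name, spec in specs.items():
        if spec.condition not in averages:
            raise KeyError(f"missing {spec.condition!r} average required for {name}")
        out[name] = measure_component(averages[spec.condition], spec)
    return out


def measures_to_values(measures: dict[str, ComponentMeasure]) -> dict[str, float]:
    """Flatten component measures into the six scalar measure ids.

    Raises if any component was not found; callers wanting partial
    results should inspect ``found`` first.
    """
    out = {}
    for name, m in measures.items():
        if not m.found:
            raise ValueError(f"component {name} not found; no scalar measures")
        out[f"{name}_amplitude"] = float(m.amplitude)
        out[f"{name}_latency"] = float(m.latency)
    return out


def specs_with_windows(windows: dict[str, tuple[float, float]]) -> dict[str, ComponentSpec]:
    """Default specs with per-component windows overridden (config files)."""
    out = dict(DEFAULT_SPECS)
    for name, win in windows.items():
        if name not in out:
            raise KeyError(f"unknown component {name}")
        out[name] = replace(out[name], window_ms=(float(win[0]), float(win[1])))
    return out
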