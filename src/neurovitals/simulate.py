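"""Synthetic event-marked EEG with embedded N100 / P300 / N400 components.

The generator plays the role of the acquisition hardware plus a
participant: each stimulus event adds a Gaussian-windowed component
waveform to the scalp channels with a fixed topographic weighting,
per-trial amplitude/latency variability, on top of 1/f background noise,
a 10 Hz alpha rhythm, 60 Hz line interference, and stereotyped blinks on
the EOG channels that propagate to the scalp with a frontal gradient.

Responses follow a differential model so that condition contrasts exist
in the raw single-condition averages (no subtraction is used downstream):

* deviant tones evoke a full N100 followed by a P300;
* standard tones evoke an attenuated N100 only (50%);
* incongruent target words evoke a full N400;
* congruent target words evoke a reduced N400 (30%);
* prime words evoke nothing.

Group presets carry the published young / older adult means and SDs for
component amplitudes and latencies; SDs act between participants, while
trial-to-trial scatter is controlled separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import DEFAULT_CHANNELS, DEFAULT_FS, EEGRecording, SCALP_CHANNELS
from .sequence import StimulusSequence, sequence_to_event_table

COMPONENTS = ("N100", "P300", "N400")

#: Gaussian template widths (sigma, ms): early components are sharper.
TEMPLATE_WIDTHS = {"N100": 15.0, "P300": 40.0, "N400": 50.0}

#: Fixed scalp topography gains. The measurement channel of each
#: component (see erp detection defaults) carries unit gain, so the
#: injected amplitude is what that channel sees.
SCALP_WEIGHTS = {
    "N100": {"Fz": 0.9, "Cz": 1.0, "Pz": 0.6},
    "P300": {"Fz": 0.5, "Cz": 0.8, "Pz": 1.0},
    "N400": {"Fz": 0.6, "Cz": 0.8, "Pz": 1.0},
}

#: Differential-response attenuation for the non-target conditions.
STANDARD_N100_GAIN = 0.5
CONGRUENT_N400_GAIN = 0.3

#: Trial-level variability: amplitude scatter as a fraction of the mean
#: magnitude, latency scatter in ms.
TRIAL_AMPLITUDE_CV = 0.30
TRIAL_LATENCY_SD = 8.0

#: Latency search windows (ms); drawn participant latencies are clamped
#: inside these with a margin so a response is always measurable.
LATENCY_CLAMP = {"N100": (75.0, 165.0), "P300": (255.0, 495.0), "N400": (310.0, 690.0)}


@dataclass
class ComponentParams:
    """One participant's parameters for one ERP component."""

    mean_amplitude: float  # microvolts, signed (N100/N400 negative)
    mean_latency: float  # ms post-stimulus
    trial_amplitude_sd: float
    trial_latency_sd: float
    scalp_weights: dict[str, float] = field(default_factory=dict)
    width: float = 40.0  # Gaussian sigma, ms


@dataclass
class ParticipantParams:
    N100: ComponentParams
    P300: ComponentParams
    N400: ComponentParams

    def component(self, name: str) -> ComponentParams:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {c: asdict(self.component(c)) for c in COMPONENTS}


@dataclass
class NoiseParams:
    """Background noise model. Amplitudes in microvolts.

    ``pink_noise_sd`` sets the RMS of the 1/f background per channel;
    alpha and line terms are sinusoid amplitudes; blinks are half-cosine
    deflections on the vertical EOG propagated to the scalp.
    """

    pink_noise_sd: float = 5.0
    alpha_amplitude: float = 2.0
    line_amplitude: float = 2.0
    blink_rate: float = 10.0  # events / minute
    blink_amplitude: float = 150.0  # on EOGv
    blink_propagation: dict[str, float] = field(
        default_factory=lambda: {"Fz": 0.4, "Cz": 0.2, "Pz": 0.1}
    )

    def validate(self) -> None:
        vals = [self.pink_noise_sd, self.alpha_amplitude, self.line_amplitude,
                self.blink_rate, self.blink_amplitude]
        if any(v < 0 for v in vals) or any(v < 0 for v in self.blink_propagation.values()):
            raise ValueError("noise parameters must be non-negative")


#: Group presets: (mean amplitude uV, between-participant amplitude SD,
#: mean latency ms, between-participant latency SD). Published group
#: summaries for young (20-30) and older (50-85) adults; N100 latency SD
#: is not reported and is fixed at 10 ms.
_PRESETS = {
    "young": {
        "N100": (-6.74, 2.13, 100.0, 10.0),
        "P300": (11.09, 3.39, 276.00, 20.59),
        "N400": (-5.93, 3.60, 460.67, 65.11),
    },
    "older": {
        "N100": (-6.74, 2.13, 100.0, 10.0),
        "P300": (10.36, 1.91, 310.00, 15.02),
        "N400": (-4.51, 1.00, 516.67, 57.53),
    },
}


@dataclass(frozen=True)
class ComponentPreset:
    mean_amplitude: float
    amplitude_sd: float  # between-participant
    mean_latency: float
    latency_sd: float  # between-participant


@dataclass(frozen=True)
class GroupPreset:
    group: str
    N100: ComponentPreset
    P300: ComponentPreset
    N400: ComponentPreset

    def component(self, name: str) -> ComponentPreset:
        return getattr(self, name)


def preset(group: str) -> GroupPreset:
    """Return the published group-level component statistics."""
    try:
        rows = _PRESETS[group]
    except KeyError as exc:
        raise ValueError(f"unknown group {group!r}; expected 'young' or 'older'") from exc
    comps = {c: ComponentPreset(*rows[c]) for c in COMPONENTS}
    return GroupPreset(group=group, **comps)


def _mean_params(p: GroupPreset) -> ParticipantParams:
    comps = {}
    for c in COMPONENTS:
        cp = p.component(c)
        comps[c] = ComponentParams(
            mean_amplitude=cp.mean_amplitude,
            mean_latency=cp.mean_latency,
            trial_amplitude_sd=TRIAL_AMPLITUDE_CV * abs(cp.mean_amplitude),
            trial_latency_sd=TRIAL_LATENCY_SD,
            scalp_weights=dict(SCALP_WEIGHTS[c]),
            width=TEMPLATE_WIDTHS[c],
        )
    return ParticipantParams(**comps)


def draw_participant(
    group_preset: GroupPreset,
    rng: np.random.Generator,
    between_participant: bool = True,
) -> ParticipantParams:
    """Draw one participant's parameters from a group preset.

    Amplitude draws keep the component's sign (magnitude floored at
    0.5 uV); latency draws are clamped inside the detection window so
    every simulated participant has a measurable response.
    """
    params = _mean_params(group_preset)
    if not between_participant:
        return params
    for c in COMPONENTS:
        cp = group_preset.component(c)
        comp = params.component(c)
        sign = math.copysign(1.0, cp.mean_amplitude)
        mag = abs(rng.normal(cp.mean_amplitude, cp.amplitude_sd))
        comp.mean_amplitude = sign * max(mag, 0.5)
        lo, hi = LATENCY_CLAMP[c]
        comp.mean_latency = float(np.clip(rng.normal(cp.mean_latency, cp.latency_sd), lo, hi))
        comp.trial_amplitude_sd = TRIAL_AMPLITUDE_CV * abs(comp.mean_amplitude)
    return params


def component_template(
    amplitude: float,
    latency: float,
    width: float,
    times_ms: np.ndarray,
) -> np.ndarray:
    """Gaussian-windowed component bump.

    Peaks at ``latency`` with signed extremum ``amplitude``; identically
    zero outside latency +/- 3*width.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    t = np.asarray(times_ms, dtype=float)
    out = amplitude * np.exp(-0.5 * ((t - latency) / width) ** 2)
    out[np.abs(t - latency) > 3.0 * width] = 0.0
    return out


def _pink_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise via spectral weighting of white noise.

    Power falls as 1/f above 1 Hz and is flat below, mimicking the broad
    background EEG spectrum after high-pass acquisition.
    """
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec * scale, n)
    x *= sd / x.std()
    return x


def _blink_waveform(fs: float, amplitude: float) -> np.ndarray:
    """400 ms half-cosine (raised-cosine) blink deflection."""
    n = int(round(0.400 * fs))
    phase = np.linspace(0.0, np.pi, n)
    return amplitude * np.sin(phase) ** 2


_RESPONSE_MAP = {
    # (code, condition) -> list of (component, gain)
    ("deviant_tone", "deviant"): [("N100", 1.0), ("P300", 1.0)],
    ("standard_tone", "standard"): [("N100", STANDARD_N100_GAIN)],
    ("target_word", "incongruent"): [("N400", 1.0)],
    ("target_word", "congruent"): [("N400", CONGRUENT_N400_GAIN)],
}


def simulate_recording(
    seq: StimulusSequence,
    params: ParticipantParams,
    noise: NoiseParams | None = None,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    tail: float = 1.5,
) -> EEGRecording:
    """Simulate one run of event-marked EEG at 500 Hz.

    Channels are Fz, Cz, Pz plus vertical/horizontal EOG. The recording
    is bit-identical for a given (sequence, params, noise, seed).
    """
    if len(seq.events) == 0:
        raise ValueError("stimulus sequence is empty")
    noise = noise or NoiseParams()
    noise.validate()
    rng = np.random.default_rng(seed)

    channels = list(DEFAULT_CHANNELS)
    n = int(round((seq.duration + tail) * fs))
    data = np.zeros((len(channels), n))

    # --- background noise ---
    for i in range(len(channels)):
        data[i] += _pink_noise(n, fs, noise.pink_noise_sd, rng)
    t = np.arange(n) / fs
    if noise.alpha_amplitude > 0:
        for ch in SCALP_CHANNELS:
            phase = rng.uniform(0, 2 * np.pi)
            data[channels.index(ch)] += noise.alpha_amplitude * np.sin(2 * np.pi * 10.0 * t + phase)
    if noise.line_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        line = noise.line_amplitude * np.sin(2 * np.pi * 60.0 * t + phase)
        data += line  # common-mode line pickup on every channel

    # --- blinks ---
    if noise.blink_rate > 0 and noise.blink_amplitude > 0:
        n_blinks = rng.poisson(noise.blink_rate * seq.duration / 60.0)
        blink = _blink_waveform(fs, noise.blink_amplitude)
        starts = np.sort(rng.integers(0, max(n - blink.size, 1), size=n_blinks))
        eogv = channels.index("EOGv")
        for s in starts:
            stop = min(s + blink.size, n)
            seg = blink[: stop - s]
            data[eogv, s:stop] += seg
            for ch, gain in noise.blink_propagation.items():
                if ch in channels:
                    data[channels.index(ch), s:stop] += gain * seg

    # --- evoked responses ---
    epoch_ms = np.arange(0, 901, 1000.0 / fs)  # template support, 0..900 ms
    for event in seq.events:
        responses = _RESPONSE_MAP.get((event.code, event.condition))
        if not responses:
            continue
        start = int(math.floor(event.onset_time * fs + 0.5))
        stop = min(start + epoch_ms.size, n)
        if start >= n:
            continue
        for comp_name, gain in responses:
            comp = params.component(comp_name)
            amp = rng.normal(comp.mean_amplitude, comp.trial_amplitude_sd) * gain
            lat = rng.normal(comp.mean_latency, comp.trial_latency_sd)
            template = component_template(amp, lat, comp.width, epoch_ms)
            for ch, weight in comp.scalp_weights.items():
                idx = channels.index(ch)
                data[idx, start:stop] += weight * template[: stop - start]

    events = sequence_to_event_table(seq, fs)
    meta = {
        "seed": int(seed),
        "fs": fs,
        "params": params.to_dict(),
        "noise": asdict(noise),
        "sequence_seed": seq.config.seed,
    }
    return EEGRecording(data=data, channels=channels, fs=fs, events=events, meta=meta)


@dataclass
class CohortMember:
    participant: str
    params: ParticipantParams
    recordings: list[EEGRecording]


def generate_cohort(
    n: int,
    group: str = "young",
    noise: NoiseParams | None = None,
    seed: int = 0,
    n_runs: int = 3,
    sequence_config=None,
    between_participant: bool = True,
) -> list[CohortMember]:
    """Simulate a cohort: each participant gets one parameter draw from
    the group preset and ``n_runs`` independently noisy runs (default 3,
    the standard session protocol)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from .sequence import SequenceConfig, build_sequence  # local to avoid cycle at import

    gp = preset(group)
    master = np.random.default_rng(seed)
    members: list[CohortMember] = []
    for i in range(n):
        params = draw_participant(gp, master, between_participant=between_participant)
        recs = []
        for r in range(n_runs):
            seq_seed = int(master.integers(0, 2**31 - 1))
            run_seed = int(master.integers(0, 2**31 - 1))
            cfg = sequence_config or SequenceConfig()
            seq = build_sequence(SequenceConfig(**{**cfg.__dict__, "seed": seq_seed}))
            rec = simulate_recording(seq, params, noise=noise, seed=run_seed)
            rec.meta["participant"] = f"{group}{i:02d}"
            rec.meta["run"] = r
            recs.append(rec)
        members.append(CohortMember(participant=f"{group}{i:02d}", params=params, recordings=recs))
    return members
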