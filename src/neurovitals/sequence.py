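"""Interlaced auditory stimulus sequence: spoken word pairs plus tone oddball.

Each 5 s cycle presents one prime-target word pair followed by a short
train of tones. Tones split into frequent standards (75 dB) and rare
deviants (100 dB, 20%); word pairs split evenly into semantically
congruent and incongruent primes. Interlacing the two streams packs close
to the maximum number of trials into a 5-minute run (60 cycles).

Counts are exact, not sampled: a default run contains exactly 48 deviant
tones out of 240 and exactly 30 incongruent pairs out of 60. Onsets are
jittered uniformly to decorrelate stimulation from ongoing alpha rhythm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Stimulus durations in seconds (tones fixed; word duration a design choice).
TONE_DURATION = 0.100
WORD_DURATION = 0.600
#: Minimum silent gap between consecutive stimuli, seconds.
MIN_GAP = 0.200

#: Stimulus intensities carried as metadata only (dB SPL); no audio synthesis.
STANDARD_DB = 75
DEVIANT_DB = 100

CODES = ("standard_tone", "deviant_tone", "prime_word", "target_word")
CONDITIONS = ("standard", "deviant", "congruent", "incongruent")


@dataclass(frozen=True)
class StimulusEvent:
    """A single timed stimulus."""

    onset_time: float  # seconds from sequence start
    code: str
    condition: str
    cycle_index: int


@dataclass(frozen=True)
class SequenceConfig:
    """Parameters of the interlaced sequence.

    Defaults give the 5 s/cycle x 60 cycle = 5 min run with 20% deviant
    tones and 50% incongruent word pairs.
    """

    n_cycles: int = 60
    cycle_duration: float = 5.0
    tones_per_cycle: int = 4
    deviant_fraction: float = 0.20
    incongruent_fraction: float = 0.50
    jitter_width: float = 0.050  # uniform +/- jitter on each onset, seconds
    seed: int = 0

    def validate(self) -> None:
        if self.n_cycles < 1 or self.tones_per_cycle < 1:
            raise ValueError("n_cycles and tones_per_cycle must be >= 1")
        if not (0.0 < self.deviant_fraction < 1.0):
            raise ValueError("deviant_fraction must be in (0, 1)")
        if not (0.0 < self.incongruent_fraction < 1.0):
            raise ValueError("incongruent_fraction must be in (0, 1)")
        if self.jitter_width < 0:
            raise ValueError("jitter_width must be >= 0")
        layout = _cycle_layout(self)
        last_onset = layout[-1]
        if last_onset + TONE_DURATION + self.jitter_width > self.cycle_duration:
            raise ValueError(
                "events do not fit in cycle_duration "
                f"(last onset {last_onset:.3f}s + tone + jitter exceeds "
                f"{self.cycle_duration}s)"
            )
        gaps = np.diff(layout)
        min_required = TONE_DURATION + MIN_GAP  # tightest pair is tone-tone
        if np.any(gaps < min_required - 1e-9):
            raise ValueError("stimuli overlap: inter-onset gap too small")

    @property
    def total_duration(self) -> float:
        return self.n_cycles * self.cycle_duration


@dataclass
class StimulusSequence:
    """Ordered, timed stimulus events plus the config that produced them."""

    events: list[StimulusEvent]
    config: SequenceConfig

    @property
    def duration(self) -> float:
        return self.config.total_duration

    def of_code(self, code: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.code == code]

    def __len__(self) -> int:
        return len(self.events)


def _cycle_layout(config: SequenceConfig) -> np.ndarray:
    """Nominal within-cycle onsets: prime, target, then the tone train."""
    prime = 0.0
    target = WORD_DURATION + MIN_GAP
    tone_start = target + WORD_DURATION + MIN_GAP
    span = config.cycle_duration - tone_start
    if span <= 0:
        raise ValueError("cycle too short for the word pair")
    spacing = span / config.tones_per_cycle
    tones = tone_start + spacing * np.arange(config.tones_per_cycle)
    return np.concatenate([[prime, target], tones])


def _round_count(n: int, fraction: float) -> int:
    """Round half away from zero (counts are non-negative here)."""
    return int(math.floor(n * fraction + 0.5))


def build_sequence(config: SequenceConfig | None = None) -> StimulusSequence:
    """Build the interlaced tone/word-pair sequence.

    Deviant tones and incongruent pairs are placed by sampling without
    replacement under a fixed seed, with the constraint that the very
    first tone is a standard (deviance is undefined before any standard
    has been heard). Every onset receives independent uniform jitter of
    +/- ``jitter_width``; the sequence is deterministic given the seed.
    """
    config = config or SequenceConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_tones = config.n_cycles * config.tones_per_cycle
    n_deviant = _round_count(n_tones, config.deviant_fraction)
    if n_deviant >= n_tones:
        raise ValueError("deviant_fraction leaves no standard tones")
    # first tone of the whole sequence stays standard
    deviant_slots = set(rng.choice(np.arange(1, n_tones), size=n_deviant, replace=False).tolist())

    n_incong = _round_count(config.n_cycles, config.incongruent_fraction)
    incong_cycles = set(rng.choice(config.n_cycles, size=n_incong, replace=False).tolist())

    layout = _cycle_layout(config)
    events: list[StimulusEvent] = []
    tone_counter = 0
    for cycle in range(config.n_cycles):
        base = cycle * config.cycle_duration
        jitter = rng.uniform(-config.jitter_width, config.jitter_width, size=layout.size)
        onsets = base + layout + jitter
        onsets[0] = max(onsets[0], 0.0)
        pair_cond = "incongruent" if cycle in incong_cycles else "congruent"
        events.append(StimulusEvent(onsets[0], "prime_word", pair_cond, cycle))
        events.append(StimulusEvent(onsets[1], "target_word", pair_cond, cycle))
        for k in range(config.tones_per_cycle):
            if tone_counter in deviant_slots:
                code, cond = "deviant_tone", "deviant"
            else:
                code, cond = "standard_tone", "standard"
            events.append(StimulusEvent(onsets[2 + k], code, cond, cycle))
            tone_counter += 1

    onset_arr = np.array([e.onset_time for e in events])
    if np.any(np.diff(onset_arr) <= 0):
        raise RuntimeError("jitter produced non-increasing onsets")  # pragma: no cover
    return StimulusSequence(events=events, config=config)


def sequence_to_event_table(seq: StimulusSequence, sample_rate: float) -> pd.DataFrame:
    """Convert onsets to a 0-based sample-index event table.

    Sample indices use round-half-away-from-zero so an onset exactly
    between two samples maps to the later one.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    rows = [
        {
            "sample_index": int(math.floor(e.onset_time * sample_rate + 0.5)),
            "code": e.code,
            "condition": e.condition,
            "cycle_index": e.cycle_index,
        }
        for e in seq.events
    ]
    return pd.DataFrame(rows, columns=["sample_index", "code", "condition", "cycle_index"])


def config_from_mapping(mapping: dict) -> SequenceConfig:
    """Build a SequenceConfig from a plain dict (YAML/JSON-loaded)."""
    known = {f for f in SequenceConfig.__dataclass_fields__}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown sequence config keys: {sorted(unknown)}")
    return replace(SequenceConfig(), **mapping)
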