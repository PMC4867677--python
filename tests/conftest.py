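"""Shared fixtures: simulated recordings and cohorts, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import neurovitals as nv


def zero_noise() -> nv.NoiseParams:
    return nv.NoiseParams(
        pink_noise_sd=0.0, alpha_amplitude=0.0, line_amplitude=0.0, blink_rate=0.0
    )


def mean_params(group: str = "young", deterministic_trials: bool = True) -> nv.ParticipantParams:
    """Preset-mean participant; optionally with zero trial-level scatter."""
    params = nv.draw_participant(
        nv.preset(group), np.random.default_rng(0), between_participant=False
    )
    if deterministic_trials:
        for c in ("N100", "P300", "N400"):
            comp = params.component(c)
            comp.trial_amplitude_sd = 0.0
            comp.trial_latency_sd = 0.0
    return params


@pytest.fixture(scope="session")
def default_sequence() -> nv.StimulusSequence:
    return nv.build_sequence(nv.SequenceConfig(seed=7))


@pytest.fixture(scope="session")
def clean_young_recording(default_sequence) -> nv.EEGRecording:
    """Noise-free run from the young preset with no trial scatter."""
    return nv.simulate_recording(default_sequence, mean_params("young"), zero_noise(), seed=3)


@pytest.fixture(scope="session")
def clean_young_averages(clean_young_recording) -> dict[str, nv.ERPWaveform]:
    epochs, _ = nv.preprocess_run(clean_young_recording)
    return nv.average_conditions(epochs)


@pytest.fixture(scope="session")
def older_cohort() -> list[nv.CohortMember]:
    """Six older-preset participants, three default-noise runs each."""
    return nv.generate_cohort(6, group="older", seed=0)


@pytest.fixture(scope="session")
def older_cohort_measures(older_cohort) -> list[dict[str, nv.ComponentMeasure]]:
    out = []
    for member in older_cohort:
        _, measures, _ = nv.process_participant(member.recordings)
        out.append(measures)
    return out
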