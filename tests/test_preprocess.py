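"""Preprocessing: filtering, ocular regression, epoching, averaging."""

import numpy as np
import pytest

import neurovitals as nv
from neurovitals.core import EEGRecording
from neurovitals.preprocess import EmptyAverageError
from tests.conftest import mean_params

FS = 500.0


def _sine_recording(freq, amplitude=10.0, duration=20.0, channels=("Fz", "Cz", "Pz")):
    t = np.arange(int(duration * FS)) / FS
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return EEGRecording(data=np.tile(x, (len(channels), 1)), channels=list(channels), fs=FS)


def _rms(x):
    return np.sqrt(np.mean(x**2))


class TestFilterRecording:
    def test_60hz_attenuated_at_least_40db(self):
        rec = _sine_recording(60.0)
        out = nv.filter_recording(rec)
        # ignore filter edges
        sl = slice(1000, -1000)
        ratio = _rms(out.data[0, sl]) / _rms(rec.data[0, sl])
        assert 20 * np.log10(ratio) < -40

    def test_10hz_passband_gain_within_1db(self):
        rec = _sine_recording(10.0)
        out = nv.filter_recording(rec)
        sl = slice(1000, -1000)
        gain_db = 20 * np.log10(_rms(out.data[0, sl]) / _rms(rec.data[0, sl]))
        assert abs(gain_db) < 1.0

    def test_dc_removed(self):
        rec = EEGRecording(data=np.full((3, 10_000), 5.0), channels=["Fz", "Cz", "Pz"], fs=FS)
        out = nv.filter_recording(rec)
        assert np.abs(out.data[:, 1000:-1000]).max() < 1e-6

    def test_zero_phase_peak_not_shifted(self):
        """A component peak must not move through the filter chain."""
        t_ms = np.arange(0, 4000, 1000 / FS)
        bump = nv.component_template(8.0, 2000.0, 40.0, t_ms)
        rec = EEGRecording(data=np.tile(bump, (3, 1)), channels=["Fz", "Cz", "Pz"], fs=FS)
        out = nv.filter_recording(rec)
        assert abs(t_ms[np.argmax(out.data[0])] - 2000.0) <= 2.0  # one sample

    def test_band_outside_nyquist_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError):
            nv.filter_recording(rec, band=(1.0, 300.0))


class TestOcularCorrect:
    def test_simulated_blinks_removed_from_fz(self, default_sequence):
        noise = nv.NoiseParams(pink_noise_sd=0.5, alpha_amplitude=0, line_amplitude=0,
                               blink_rate=15.0)
        params = mean_params("young")
        for c in ("N100", "P300", "N400"):
            params.component(c).mean_amplitude = 0.0
        rec = nv.simulate_recording(default_sequence, params, noise, seed=21)
        filt = nv.filter_recording(rec, band=(0.5, 30.0), notch=None)
        corrected = nv.ocular_correct(filt)
        before = np.abs(filt.get("Fz")).max()
        after = np.abs(corrected.get("Fz")).max()
        assert after < 0.10 * before

    def test_zero_eog_leaves_recording_unchanged(self):
        rng = np.random.default_rng(0)
        data = np.vstack([rng.standard_normal((3, 5000)), np.zeros((2, 5000))])
        rec = EEGRecording(data=data, channels=["Fz", "Cz", "Pz", "EOGv", "EOGh"], fs=FS)
        out = nv.ocular_correct(rec)
        assert np.allclose(out.data[:3], rec.data[:3])

    def test_uncorrelated_eog_coefficients_near_zero(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((5, 200_000))
        rec = EEGRecording(data=data, channels=["Fz", "Cz", "Pz", "EOGv", "EOGh"], fs=FS)
        out = nv.ocular_correct(rec)
        for coeffs in out.meta["ocular_correction"]["coefficients"].values():
            assert all(abs(b) < 0.05 for b in coeffs)

    def test_missing_eog_warns_and_passes_through(self):
        rec = _sine_recording(10.0)
        with pytest.warns(UserWarning):
            out = nv.ocular_correct(rec)
        assert np.array_equal(out.data, rec.data)
        assert out.meta["ocular_correction"] == "skipped_no_eog"


class TestSegment:
    def test_epoch_covers_expected_samples(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 2000))
        events = nv.sequence_to_event_table(
            nv.StimulusSequence([nv.StimulusEvent(2.0, "standard_tone", "standard", 0)],
                                nv.SequenceConfig()),
            FS,
        )
        rec = EEGRecording(data=data, channels=["Fz", "Cz", "Pz"], fs=FS, events=events)
        epochs, dropped = nv.segment(rec)
        assert dropped == 0
        assert len(epochs) == 1
        assert epochs[0].data.shape == (3, 501)
        assert np.array_equal(epochs[0].data, data[:, 950:1451])
        assert epochs[0].times_ms[0] == -100.0 and epochs[0].times_ms[-1] == 900.0

    def test_event_too_early_is_dropped_and_counted(self):
        data = np.zeros((3, 2000))
        seq = nv.StimulusSequence(
            [nv.StimulusEvent(0.02, "standard_tone", "standard", 0)], nv.SequenceConfig()
        )
        rec = EEGRecording(data=data, channels=["Fz", "Cz", "Pz"], fs=FS,
                           events=nv.sequence_to_event_table(seq, FS))
        epochs, dropped = nv.segment(rec)
        assert (len(epochs), dropped) == (0, 1)

    def test_default_sequence_epoch_counts(self, clean_young_recording):
        epochs, dropped = nv.segment(clean_young_recording)
        assert dropped == 0
        tone = [e for e in epochs if e.condition in ("standard", "deviant")]
        word = [e for e in epochs if e.condition in ("congruent", "incongruent")]
        assert (len(tone), len(word)) == (240, 60)


class TestBaselineCorrect:
    def _epoch(self, data):
        times = np.arange(-50, 451) * 1000.0 / FS
        return nv.Epoch(condition="deviant", data=data, channels=["Fz", "Cz", "Pz"],
                        times_ms=times, event_index=0)

    def test_constant_offset_removed(self):
        ep = self._epoch(np.full((3, 501), 5.0))
        nv.baseline_correct(ep)
        assert np.abs(ep.data[:, :50]).max() < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ep = self._epoch(rng.standard_normal((3, 501)))
        nv.baseline_correct(ep)
        once = ep.data.copy()
        nv.baseline_correct(ep)
        assert np.allclose(ep.data, once)

    def test_ramp_shifted_by_prestimulus_mean(self):
        ramp = np.tile(np.arange(501, dtype=float), (3, 1))
        ep = self._epoch(ramp.copy())
        nv.baseline_correct(ep)
        # baseline samples are 0..49 (times < 0): mean 24.5
        assert np.allclose(ep.data, ramp - 24.5)


class TestRejectAndAverage:
    def _epochs(self, n, scale=1.0, condition="deviant", seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(-50, 451) * 1000.0 / FS
        return [
            nv.Epoch(condition=condition, data=scale * rng.standard_normal((3, 501)),
                     channels=["Fz", "Cz", "Pz"], times_ms=times, event_index=i)
            for i in range(n)
        ]

    def test_large_amplitude_epoch_rejected(self):
        eps = self._epochs(2)
        eps[0].data[0, 250] = 150.0
        nv.reject_artifacts(eps, threshold=100.0)
        assert eps[0].rejected and not eps[1].rejected

    def test_infinite_threshold_rejects_nothing(self):
        eps = self._epochs(10, scale=50.0)
        nv.reject_artifacts(eps, threshold=np.inf)
        assert not any(e.rejected for e in eps)

    def test_eog_amplitude_does_not_reject(self):
        times = np.arange(-50, 451) * 1000.0 / FS
        data = np.zeros((5, 501))
        data[3] = 200.0  # EOGv
        ep = nv.Epoch(condition="deviant", data=data,
                      channels=["Fz", "Cz", "Pz", "EOGv", "EOGh"], times_ms=times, event_index=0)
        nv.reject_artifacts([ep], threshold=100.0)
        assert not ep.rejected

    def test_average_of_identical_epochs_is_the_epoch(self):
        eps = self._epochs(1)
        clones = [nv.Epoch(e.condition, e.data.copy(), e.channels, e.times_ms, i)
                  for i, e in enumerate(eps * 5)]
        avg = nv.conditional_average(clones, "deviant")
        assert np.allclose(avg.data, eps[0].data)
        assert avg.n_accepted == 5

    def test_rejected_epochs_contribute_nothing(self):
        eps = self._epochs(6)
        eps[0].rejected = True
        avg_with = nv.conditional_average(eps, "deviant")
        avg_without = nv.conditional_average(eps[1:], "deviant")
        assert np.allclose(avg_with.data, avg_without.data)
        assert avg_with.n_rejected == 1

    def test_empty_average_raises(self):
        with pytest.raises(EmptyAverageError):
            nv.conditional_average(self._epochs(3, condition="standard"), "deviant")

    def test_noise_averages_down_as_inverse_sqrt_n(self):
        """RMS of the averaged noise scales ~ N^-0.5 (log-log slope)."""
        rms = []
        ns = [10, 40, 160]
        for n in ns:
            eps = self._epochs(n, seed=42)
            avg = nv.conditional_average(eps, "deviant")
            rms.append(np.sqrt(np.mean(avg.data**2)))
        slope = np.polyfit(np.log(ns), np.log(rms), 1)[0]
        assert abs(slope + 0.5) < 0.1


def test_pipeline_deterministic(clean_young_recording):
    e1, _ = nv.preprocess_run(clean_young_recording)
    e2, _ = nv.preprocess_run(clean_young_recording)
    a1 = nv.conditional_average(e1, "deviant")
    a2 = nv.conditional_average(e2, "deviant")
    assert np.array_equal(a1.data, a2.data)
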