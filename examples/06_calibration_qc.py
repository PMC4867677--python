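"""Hardware-calibration QC on a known multi-sine test signal.

A 5/10/15/30 Hz equal-amplitude test signal is "re-recorded" with line
noise and drift across sessions; the report gives spectral SNR,
inter-channel correlation and day-over-day peak-voltage stability.
"""

import numpy as np

import neurovitals as nv

rng = np.random.default_rng(3)
fs = 500.0
sessions = []
for day_gain in (1.00, 1.01, 0.99, 1.02):  # slight session-to-session drift
    clean = day_gain * nv.make_test_signal(duration=30.0, fs=fs)
    t = np.arange(clean.size) / fs
    line = 0.2 * np.sin(2 * np.pi * 60.0 * t)
    ch1 = clean + line + 0.05 * rng.standard_normal(clean.size)
    ch2 = clean + line + 0.05 * rng.standard_normal(clean.size)
    sessions.append(np.vstack([ch1, ch2]))

report = nv.stability_metrics(sessions, fs=fs)
print(f"SNR (signal tones vs 60 Hz) : {report.snr:.1f}")
print(f"inter-channel correlation   : {report.interchannel_r:.4f}")
print(f"day-over-day change         : {report.day_over_day_change:.2f}%")
print(f"session peak-to-peak (V)    : {[round(p, 3) for p in report.peak_to_peak]}")
# SNR ~ 100 here (4 unit tones vs one 0.2-amplitude line tone: 4/0.04);
# stability within a couple of percent indicates trustworthy hardware.
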