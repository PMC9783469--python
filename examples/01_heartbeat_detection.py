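"""Detect heartbeat peaks in a simulated pulse-oximeter trace.

Generates 220 s of quasi-periodic PPG at 60 bpm with 10 ms beat-to-beat
jitter, detects the systolic peaks (5 Hz zero-phase low-pass, autocorrelation
period estimate, minimum peak distance 70% of the period) and summarizes
beat-to-beat variability with 20 s-window RMSSD.
"""

import numpy as np

import brainbeat as bb

cfg = bb.SimConfig(seed=0)
trace, truth = bb.generate_ppg(cfg)
peaks = bb.detect_peaks(trace)
hrv = bb.rmssd_hrv(peaks, trace_bounds=(0.0, cfg.duration))

offsets = np.abs(peaks.peak_times[:, None] - truth.peak_times[None, :]).min(axis=1)
print(f"true beats:      {truth.peak_times.size}")
print(f"detected beats:  {peaks.n_peaks}")
print(f"cycle estimate:  {peaks.cycle_estimate:.3f} s "
      f"(mean heart rate {peaks.mean_heart_rate:.1f} bpm)")
print(f"worst timing error vs truth: {1000 * offsets.max():.1f} ms")
print(f"max 20 s-window RMSSD: {hrv.max_rmssd:.1f} ms "
      f"({'passes' if hrv.passes_threshold else 'fails'} the 50 ms check)")
print()
print("The RMSSD check confirms beat timing varies less than one 50 ms slice")
print("window, so samples can be pooled across beats without time-warping.")
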