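"""Cardiac-gated waveform of a single voxel by peak-relative binning.

A noiseless artery-like voxel (sharp dip 0.15 cycle before the PPG peak) is
sampled every TR = 250 ms at its slice's acquisition offset; assigning each
sample its time relative to the heartbeat peaks and averaging into 50 ms
bins recovers the waveform, and the even/odd-beat split gives the
zero-referenced test–retest R².
"""

import numpy as np

import brainbeat as bb

cfg = bb.SimConfig(seed=0)
trace, truth = bb.generate_ppg(cfg)
peaks = bb.detect_peaks(trace)
timing = cfg.timing

slice_idx = 13
t = (np.arange(timing.n_volumes - 3) + 3) * timing.tr + timing.slice_offsets[slice_idx]
prev = np.clip(np.searchsorted(truth.peak_times, t, side="right") - 1, 0, None)
signal = bb.waveform_template("artery")((t - truth.peak_times[prev]) / truth.cycle)
vox = bb.VoxelSeries(signal, t)

resp = bb.align_to_peaks(vox, peaks, timing)
ok = np.isfinite(resp.even_mean) & np.isfinite(resp.odd_mean)
print(f"bins in the [-0.5, 1.0) cycle window: {resp.n_bins} "
      f"({int(round(truth.cycle / timing.slice_duration))} per cycle)")
print(f"bins populated in both halves: {ok.sum()}")
print(f"test-retest R^2: {resp.r2:.1f}")
print()
print("cycle-fraction   even-beat mean   odd-beat mean   (percent modulation)")
for f, e, o in zip(resp.bin_centers_frac[ok][:12], resp.even_mean[ok][:12], resp.odd_mean[ok][:12]):
    print(f"   {f:+.3f}          {e:+.3f}          {o:+.3f}")
print()
print("The dip near cycle fraction -0.15 is the arterial pulse arriving in the")
print("brain before it reaches the fingertip PPG; R^2 near 100 means the even-")
print("and odd-beat averages agree almost perfectly.")
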