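# Methods

## Signal model and assumptions

The package treats the fMRI signal of each voxel as a baseline plus a
waveform locked to the cardiac cycle plus slow drift and thermal noise. The
central assumption is beat-to-beat consistency: the cardiac-gated waveform
is the same for every beat within a run, so samples can be pooled across
beats without per-beat time warping. This is justified only when heart-rate
variability is small relative to the temporal resolution; the RMSSD check
(20 s windows, pass threshold 50 ms = one slice-acquisition window) makes
that precondition explicit and machine-checkable. Slice timing is treated
as signal, not artifact — no slice-timing correction is applied, because
each slice's acquisition offset is exactly what places its samples within
the cardiac cycle.

## Heartbeat detection

The PPG trace is filtered with a third-order Butterworth low-pass at 5 Hz
applied forward and backward (zero net phase, squared magnitude response).
The heartbeat period is the lag of the highest autocorrelation peak within
a physiological band (default 40–150 bpm; the band excludes the zero-lag
peak and harmonics, and the peak must reach 20% of the zero-lag value so
white noise is rejected). Peaks are local maxima with minimum separation
0.7 × period, prominence ≥ 25% of the filtered signal's interquartile
range, and height ≥ median + 25% IQR. The height floor is a robustness
addition: in pulse-free stretches of a recording (before the first or
after the last beat) filtered noise produces maxima that satisfy the
prominence rule alone. Autocorrelation is computed on the filtered trace
(configurable).

Even/odd beat parity is assigned by index in time order, even = {0, 2, …};
the convention is arbitrary and the test suite checks that swapping it
moves reliable-voxel R² by < 5 points.

## Alignment and binning

Percent modulation is computed per voxel as 100·(x − mean)/mean after
dropping `n_drop = 3` volumes, then the least-squares line is removed
(conversion before detrending, in that order). Voxels with non-positive
temporal mean are background and are masked, not errors.

Each sample is assigned to every heartbeat peak whose epoch window —
cycle fraction [−0.5, 1.0) by default — contains it; with this window a
sample belongs to at most two beats (the tail of one epoch overlaps the
head of the next), and samples beyond a beat's own interval still
contribute to late bins (no censoring at the next peak). Bins are
`slice_duration` wide in seconds relative to the peak; cycle fraction uses
the global autocorrelation period, not per-beat intervals. Within a bin,
samples are averaged with equal weight (not per-beat weighting).

Bin centers are *empirical*: the count-weighted mean sample time within
the bin, pooled over parities, with the geometric center as fallback for
empty bins. When the cardiac period is commensurate with the TR, samples
cluster at a few phases per bin and can sit up to half a bin from the
geometric center; empirical centers make the noiseless-sinusoid oracle
(binned waveform = sinusoid at bin centers) exact for every slice offset.

R² uses pairwise-complete bins only; a voxel with Σy² = 0 or fewer than
two complete bins has undefined reliability and is masked. For pure noise
the even and odd halves are independent, so E[Σ(y−f)²] = 2·E[Σy²] and the
zero-referenced R² centers at −100; null voxels are therefore separated
from signal by falling far *below* the display threshold, not by sitting
near zero.

## Resampling to the cycle-fraction grid

Waveforms are interpolated onto 128 evenly spaced cycle-fraction points on
[−0.5, 1.0). Three methods are provided. Linear interpolation (function
default) reproduces affine segments exactly but pins every local extremum
of the resampled curve to a bin center, quantizing extremum timing to the
bin width; worse, bin values are window *averages*, and averaging a
fast-onset/slow-return transient over a window of width h shifts its
extremum toward the shallow side by ≈ (w_ret − w_on)/(w_ret + w_on) · h/2
(+0.0125 cycle for the default template widths at h = 0.05). The pipeline's
timing path therefore uses a mean-preserving histospline: a natural cubic
spline through the cumulative integral of the bin averages, differentiated,
which undoes the first-order smear and restores sub-bin extremum
resolution. A plain natural cubic spline is also available. Out-of-range
grid points take the edge value.

## SVD model

Each retained waveform row is unit-normalized and multiplied by max(R², 0),
so row norms equal R² exactly and unreliable voxels are down-weighted;
voxels with non-positive or undefined R² are pruned rather than entered
with flipped sign. No mean-centering is applied before the SVD (rows are
already zero-mean percent signals). Component signs are fixed
deterministically: each time course is negative at cycle fraction 0 (blood
dips at the PPG peak); if its value there is numerically zero, the sign of
its largest-magnitude element decides. Cross-validated variance explained
projects the even-half matrix onto the span of the first k odd-half
components; the default component count k = 2 follows the smallest-k-over-
70% rule and is configurable. Canonical components across subjects come
from a second SVD of the stacked (unit-normalized) per-subject components
with one subject held out; a single training subject degenerates to that
subject's components with a warning.

β weights are inner products (the components are orthonormal), Rrmse is
RMS(even − predicted)/RMS(even − odd) with 0/0 defined as 0 and x/0 as
infinity. Extrema are located on the grid inside a search window (default
−0.5 to 0.66 cycle) and refined by 3-point parabolic interpolation, skipped
at window edges; ties break toward the earliest time; flat waveforms are
masked.

## Synthetic data

The generator emulates the study conditions: 60 bpm heart rate, 10 ms
i.i.d. beat-to-beat jitter, 220 s of 100 Hz PPG, 8×8×40 voxels with SMS
timing (TR 250 ms, 40 slices in 5 groups of 8, 878 volumes), and a slow
variant (TR 2 s, 45 sequential slices, 240 volumes, 480 s). On top of the
i.i.d. jitter, the heartbeat period carries a slow sinusoidal modulation
(±3%, ~90 s period, random phase) — the heart-rate meander every resting
subject shows. It adds only ~2 ms to RMSSD but sweeps each slice's sampling
phase across the cycle; without it, a heart rate commensurate with the TR
would leave peak-relative bins covered only by a jitter random walk, a
degenerate sampling pattern real recordings do not produce.

The PPG pulse has a symmetric apex (Gaussian, 60 ms width) with a slow
diastolic run-off and a dicrotic bump; keeping the apex symmetric means the
5 Hz zero-phase filter moves it by only ~2 ms, so detected peaks are
essentially unbiased markers of the rendered beat.

Voxel classes carry skewed-Gaussian transients (onset width 0.06 cycle,
return width 0.18 — steep arrival, shallow return): artery sign −,
extremum −0.15 cycle, amplitude 1.5%; vein sign −, extremum 0.0, amplitude
1.0%; CSF sign +, extremum +0.05, amplitude 1.0%; null voxels are flat.
Amplitudes are percent-modulation choices placing reliable voxels in the
R² > 50 regime at the default thermal noise of 0.5% per sample (a typical
3 T, 4 mm-voxel scale); drift is 0.5% per scan. Waveforms are imposed
directly in percent units — the biophysical T1-weighting of the contrast is
*not* simulated mechanistically, so passing tests demonstrate correctness
of the alignment/modeling machinery, not of any physiological forward
model. Real data additionally contain motion, respiration and vasomotion,
none of which are simulated. A steady-state spoiled gradient-echo utility
(S = M0·sinα·(1−E1)/(1−cosα·E1)·e^(−TE/T2*)) with analytic T1/T2*
sensitivities supports sequence comparisons at reference tissue values
(T1 = 1.3 s, T2* = 40 ms, configurable).

## Numerical choices and degenerate inputs

- Autocorrelation cycle search: highest peak in-band, ≥ 0.2 normalized.
- Numerically constant traces (filter ripple ~1e−16) are treated as
  constant when deciding cycle-not-found / insufficient-beats.
- `filtfilt` default padding; traces shorter than 3·(filter length) raise
  a too-short error.
- Bin assignment uses half-open bins [edge, edge + h); samples exactly at
  the window's upper edge are excluded.
- Degenerate SVD (rank 0) and empty matrices raise model errors; k is
  capped at the matrix rank.
- Edge beats (within half a cycle of the recording boundary) are kept for
  alignment but can be excluded from RMSSD windows via `trace_bounds`.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configurations are byte-identical across runs on one platform.

## Problem sizes

The test suite and examples use the full acquisition geometry of the fast
protocol (40 slices, 878 volumes, 100 Hz physio) with an 8×8 in-plane grid
(2560 voxels), which exercises every code path at full temporal fidelity;
in-plane extent carries no additional structure, so scaling it up only
replicates voxels. The acceptance script uses 2000 simulated waveforms on
the 128-point grid.

## Known limitations

- Timing estimates carry a residual late bias of up to ~0.04 cycle for
  waveform shapes that the leading components do not span exactly
  (rank-truncation bias); it is bounded by the ±0.05-cycle (one slice
  window) resolution of the method and can be reduced by raising k.
- The epoch window, display threshold (R² > 50) and cv threshold (70%) are
  conventions, exposed as configuration.
- Cycle fraction uses the global period; runs with strong heart-rate drift
  blur late-cycle bins (the RMSSD gate is the guard).
- The ROI zone table ships only the level-1 anatomical anchors (rostral
  anterior cingulate / medial orbitofrontal → ACA, parahippocampal → PCA,
  insula / transverse temporal → MCA); full atlas-to-zone assignments are
  user-supplied.
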