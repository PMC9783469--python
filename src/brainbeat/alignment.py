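"""Retrospective cardiac alignment of fMRI time series.

Each slice of a simultaneous-multislice (SMS) acquisition is measured within
a short window (50 ms for the fast protocol), at a known offset within the
TR.  Rather than correcting slice timing, this module exploits it: every
sample of every voxel is assigned its time relative to the nearest heartbeat
peaks (PPG peak = time zero), and samples pooled over the whole acquisition
are averaged into peak-relative bins one slice-window wide.  Averaging even-
and odd-indexed beats separately gives two independent estimates of the
cardiac-gated waveform, whose agreement is scored by a zero-referenced R²:

    R² = 100 * (1 − Σᵢ (yᵢ − fᵢ)² / Σᵢ yᵢ²)

with yᵢ the even-beat and fᵢ the odd-beat bin mean — referenced to zero, not
to the mean, because the percent-modulation signal is already zero-mean and
the mean of a cardiac-gated waveform is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import signal as sp_signal

from .errors import (
    InsufficientBeatsError,
    InvalidGeometryError,
    InvalidParameterError,
    TraceTooShortError,
)
from .physio import PeakSeries

__all__ = [
    "AcquisitionTiming",
    "VoxelSeries",
    "AlignedResponse",
    "AlignedVolume",
    "slice_offsets_sms",
    "timing_from_bids",
    "percent_modulation",
    "align_to_peaks",
    "reliability_r2",
    "align_volume",
]

DEFAULT_WINDOW = (-0.5, 1.0)


@dataclass(frozen=True)
class AcquisitionTiming:
    """Slice-timing geometry of one fMRI run.

    ``slice_offsets[s]`` is the acquisition time of slice ``s`` within a TR;
    simultaneously excited slices share an offset.  ``slice_duration`` is
    the width of one acquisition window and sets the bin width for cardiac
    alignment.
    """

    tr: float
    n_slices: int
    slice_offsets: np.ndarray
    slice_duration: float
    n_volumes: int

    def __post_init__(self):
        offsets = np.asarray(self.slice_offsets, dtype=float)
        object.__setattr__(self, "slice_offsets", offsets)
        if self.tr <= 0 or self.slice_duration <= 0:
            raise InvalidParameterError("tr and slice_duration must be > 0")
        if offsets.size != self.n_slices:
            raise InvalidGeometryError("slice_offsets length must equal n_slices")
        if np.any(offsets < 0) or np.any(offsets >= self.tr):
            raise InvalidGeometryError("slice offsets must lie in [0, tr)")
        if self.n_volumes < 1:
            raise InvalidParameterError("n_volumes must be >= 1")


def slice_offsets_sms(
    tr: float, n_slices: int, mb_factor: int, n_volumes: int
) -> AcquisitionTiming:
    """Timing for an SMS/multiband acquisition with interleaved groups.

    ``n_slices`` must divide evenly into groups of ``mb_factor``
    simultaneous slices; group g is acquired at offset g·(tr/n_groups) and
    slice s belongs to group ``s mod n_groups``.  The fast protocol
    (tr 0.25 s, 40 slices, MB 8) yields 5 groups at 0/50/100/150/200 ms,
    i.e. a 50 ms slice-acquisition window.
    """
    if mb_factor < 1 or n_slices % mb_factor != 0:
        raise InvalidGeometryError(
            f"n_slices={n_slices} not divisible by mb_factor={mb_factor}"
        )
    n_groups = n_slices // mb_factor
    slice_duration = tr / n_groups
    groups = np.arange(n_slices) % n_groups
    offsets = groups * slice_duration
    return AcquisitionTiming(tr, n_slices, offsets, slice_duration, n_volumes)


def timing_from_bids(
    tr: float, slice_timing: list[float] | np.ndarray, n_volumes: int
) -> AcquisitionTiming:
    """Build timing from a BIDS ``SliceTiming`` list (seconds per slice)."""
    offsets = np.asarray(slice_timing, dtype=float)
    n_groups = np.unique(offsets).size
    if n_groups < 1:
        raise InvalidGeometryError("empty SliceTiming")
    slice_duration = tr / n_groups
    return AcquisitionTiming(tr, offsets.size, offsets, slice_duration, n_volumes)


@dataclass(frozen=True)
class VoxelSeries:
    """Percent-modulation signal of one voxel with its acquisition times."""

    values: np.ndarray
    acquisition_times: np.ndarray
    voxel_index: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.acquisition_times, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "acquisition_times", t)
        if v.shape != t.shape:
            raise InvalidGeometryError("values and acquisition_times differ in length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise InvalidParameterError("acquisition_times must be strictly increasing")


def percent_modulation(raw: np.ndarray, n_drop: int = 3) -> np.ndarray | None:
    """Percent modulation with dummy-volume removal and linear detrending.

    Drops the first ``n_drop`` volumes, converts to 100·(x − mean)/mean and
    removes the least-squares line; the output has zero mean and zero linear
    trend.  Works on 1-D series or 2-D stacks (voxels × time).  Voxels with
    non-positive temporal mean (background) return None (1-D) or NaN rows
    (2-D) rather than raising.
    """
    raw = np.asarray(raw, dtype=float)
    one_d = raw.ndim == 1
    x = raw[np.newaxis, :] if one_d else raw
    if x.shape[-1] <= n_drop + 2:
        raise TraceTooShortError(
            f"series length {x.shape[-1]} too short for n_drop={n_drop}"
        )
    x = x[:, n_drop:]
    mean = x.mean(axis=1, keepdims=True)
    good = mean[:, 0] > 0
    out = np.full(x.shape, np.nan)
    if np.any(good):
        pct = 100.0 * (x[good] - mean[good]) / mean[good]
        out[good] = sp_signal.detrend(pct, axis=-1, type="linear")
    if one_d:
        return out[0] if good[0] else None
    return out


def reliability_r2(even: np.ndarray, odd: np.ndarray) -> float:
    """Zero-referenced test–retest R² between even- and odd-beat waveforms.

    Returns ``100·(1 − Σ(yᵢ−fᵢ)²/Σyᵢ²)`` with y = even, f = odd; bounded
    above by 100, unbounded below.  NaN pairs are excluded pairwise.
    Returns NaN when Σy² = 0 (undefined reliability; the voxel should be
    masked by the caller).
    """
    y = np.asarray(even, dtype=float)
    f = np.asarray(odd, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise InvalidParameterError("even and odd must be equal-length, size >= 2")
    valid = np.isfinite(y) & np.isfinite(f)
    y, f = y[valid], f[valid]
    ss_data = float(np.sum(y**2))
    if y.size == 0 or ss_data == 0.0:
        return float("nan")
    ss_resid = float(np.sum((y - f) ** 2))
    return 100.0 * (1.0 - ss_resid / ss_data)


@dataclass(frozen=True)
class AlignedResponse:
    """Cardiac-gated waveform of one voxel.

    ``even_mean``/``odd_mean`` are per-bin averages over samples assigned to
    even-/odd-indexed beats; bins empty in either half are NaN.
    ``bin_centers_s`` are empirical centers (count-weighted mean sample time
    within each bin, pooled over parities; geometric center where empty),
    ``bin_centers_frac`` the same divided by the heartbeat period.
    """

    bin_centers_s: np.ndarray
    bin_centers_frac: np.ndarray
    even_mean: np.ndarray
    odd_mean: np.ndarray
    counts_even: np.ndarray
    counts_odd: np.ndarray
    r2: float
    voxel_index: tuple[int, int, int] = (0, 0, 0)

    @property
    def n_bins(self) -> int:
        return self.bin_centers_s.size


def _bin_assignments(
    sample_times: np.ndarray,
    peaks: PeakSeries,
    window: tuple[float, float],
    bin_width: float,
):
    """Assign each sample to (bin, beat-parity) pairs.

    A sample at time t is assigned to every peak p with (t−p)/cycle inside
    ``window``; with the default (−0.5, 1.0) window a sample can belong to
    at most two beats (the tail of one epoch overlaps the head of the
    next).  Returns (sample_idx, bin_idx, parity, rel_time) flat arrays and
    the number of bins.
    """
    cycle = peaks.cycle_estimate
    lo_s, hi_s = window[0] * cycle, window[1] * cycle
    if hi_s <= lo_s:
        raise InvalidParameterError("window must have positive extent")
    n_bins = int(np.ceil((hi_s - lo_s) / bin_width - 1e-9))
    pt = peaks.peak_times
    t = np.asarray(sample_times, dtype=float)
    base = np.searchsorted(pt, t)  # first peak strictly later than t (ties left)
    samp, bins, par, rel_all = [], [], [], []
    # candidate peaks around each sample: enough to cover a 1.5-cycle window
    for k in range(-3, 2):
        j = base + k
        ok = (j >= 0) & (j < pt.size)
        rel = np.where(ok, t - pt.clip(min=None)[np.clip(j, 0, pt.size - 1)], np.nan)
        inside = ok & (rel >= lo_s) & (rel < hi_s)
        if not np.any(inside):
            continue
        idx = np.nonzero(inside)[0]
        r = rel[idx]
        b = np.floor((r - lo_s) / bin_width).astype(int)
        b = np.clip(b, 0, n_bins - 1)
        samp.append(idx)
        bins.append(b)
        par.append(j[idx] % 2)
        rel_all.append(r)
    if not samp:
        return (
            np.empty(0, int),
            np.empty(0, int),
            np.empty(0, int),
            np.empty(0, float),
            n_bins,
            lo_s,
        )
    return (
        np.concatenate(samp),
        np.concatenate(bins),
        np.concatenate(par),
        np.concatenate(rel_all),
        n_bins,
        lo_s,
    )


def _binned_means(values2d, samp, bins, par, rel, n_bins, lo_s, bin_width, cycle):
    """Per-bin even/odd means for a stack of voxels sharing one slice timing."""
    counts = np.zeros((2, n_bins))
    np.add.at(counts, (par, bins), 1.0)
    # indicator matrices (n_samples, n_bins) per parity; sample may hit 2 bins
    n_samples = values2d.shape[1]
    ind = np.zeros((2, n_samples, n_bins))
    np.add.at(ind, (par, samp, bins), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        even = (values2d @ ind[0]) / counts[0]
        odd = (values2d @ ind[1]) / counts[1]
    even[:, counts[0] == 0] = np.nan
    odd[:, counts[1] == 0] = np.nan
    # empirical bin centers, pooled over parities
    rel_sum = np.zeros(n_bins)
    tot = np.zeros(n_bins)
    np.add.at(rel_sum, bins, rel)
    np.add.at(tot, bins, 1.0)
    geometric = lo_s + (np.arange(n_bins) + 0.5) * bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        centers = np.where(tot > 0, rel_sum / np.maximum(tot, 1), geometric)
    return even, odd, counts[0], counts[1], centers, centers / cycle


def align_to_peaks(
    voxel: VoxelSeries,
    peaks: PeakSeries,
    timing: AcquisitionTiming,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> AlignedResponse:
    """Cardiac-gated waveform of one voxel by peak-relative binning.

    Every sample is assigned its time relative to each heartbeat peak whose
    epoch ``window`` (in cycle fractions) contains it, then averaged into
    bins of width ``timing.slice_duration`` — separately for even- and
    odd-indexed beats — and scored with the zero-referenced R².
    """
    if peaks.n_peaks < 10:
        raise InsufficientBeatsError(f"{peaks.n_peaks} peaks; need >= 10")
    samp, bins, par, rel, n_bins, lo_s = _bin_assignments(
        voxel.acquisition_times, peaks, window, timing.slice_duration
    )
    even, odd, ce, co, centers_s, centers_f = _binned_means(
        voxel.values[np.newaxis, :],
        samp,
        bins,
        par,
        rel,
        n_bins,
        lo_s,
        timing.slice_duration,
        peaks.cycle_estimate,
    )
    r2 = reliability_r2(even[0], odd[0]) if np.any(ce > 0) and np.any(co > 0) else float("nan")
    return AlignedResponse(
        bin_centers_s=centers_s,
        bin_centers_frac=centers_f,
        even_mean=even[0],
        odd_mean=odd[0],
        counts_even=ce,
        counts_odd=co,
        r2=r2,
        voxel_index=voxel.voxel_index,
    )


@dataclass
class AlignedVolume:
    """Cardiac-gated waveforms for all in-mask voxels of one run.

    Per-slice quantities (bin centers, counts) are shared by all voxels in
    a slice because the binning depends only on slice timing.  ``r2_map``
    is on the input grid with NaN background.
    """

    voxel_indices: np.ndarray  # (N, 3) int
    voxel_slice: np.ndarray  # (N,) slice index of each voxel
    even: np.ndarray  # (N, n_bins)
    odd: np.ndarray  # (N, n_bins)
    r2: np.ndarray  # (N,)
    counts_even: np.ndarray  # (n_slices, n_bins)
    counts_odd: np.ndarray  # (n_slices, n_bins)
    bin_centers_s: np.ndarray  # (n_slices, n_bins)
    bin_centers_frac: np.ndarray  # (n_slices, n_bins)
    r2_map: np.ndarray  # 3-D float
    cycle_estimate: float
    window: tuple[float, float]
    affine: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def n_bins(self) -> int:
        return self.even.shape[1]

    def response(self, i: int) -> AlignedResponse:
        """The :class:`AlignedResponse` of in-mask voxel ``i``."""
        s = self.voxel_slice[i]
        return AlignedResponse(
            bin_centers_s=self.bin_centers_s[s],
            bin_centers_frac=self.bin_centers_frac[s],
            even_mean=self.even[i],
            odd_mean=self.odd[i],
            counts_even=self.counts_even[s],
            counts_odd=self.counts_odd[s],
            r2=float(self.r2[i]),
            voxel_index=tuple(self.voxel_indices[i]),
        )

    def save_r2(self, path: str | Path) -> None:
        affine = self.affine if self.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(self.r2_map.astype(np.float32), affine), str(path))

    def save_waveforms_tsv(self, path: str | Path) -> None:
        """Flat long-format store of all waveforms (one row per voxel × bin)."""
        import pandas as pd

        n, b = self.n_voxels, self.n_bins
        s = self.voxel_slice
        df = pd.DataFrame(
            {
                "i": np.repeat(self.voxel_indices[:, 0], b),
                "j": np.repeat(self.voxel_indices[:, 1], b),
                "k": np.repeat(self.voxel_indices[:, 2], b),
                "bin_center_s": self.bin_centers_s[s].ravel(),
                "bin_center_frac": self.bin_centers_frac[s].ravel(),
                "even_mean": self.even.ravel(),
                "odd_mean": self.odd.ravel(),
                "count_even": self.counts_even[s].ravel(),
                "count_odd": self.counts_odd[s].ravel(),
            }
        )
        df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def align_volume(
    fmri: "nib.Nifti1Image | np.ndarray",
    peaks: PeakSeries,
    timing: AcquisitionTiming,
    mask: np.ndarray | None = None,
    n_drop: int = 3,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> AlignedVolume:
    """Cardiac alignment of a whole 4-D run, vectorized per slice.

    Voxels with non-positive temporal mean are masked out; beyond that,
    ``mask`` restricts the analysis.  The binning geometry is computed once
    per slice (all voxels of a slice share acquisition times).
    """
    if hasattr(fmri, "get_fdata"):
        data = np.asarray(fmri.get_fdata())
        affine = fmri.affine
    else:
        data = np.asarray(fmri, dtype=float)
        affine = None
    if data.ndim != 4:
        raise InvalidGeometryError("fmri must be 4-D")
    nx, ny, nz, nv = data.shape
    if nv != timing.n_volumes:
        raise InvalidGeometryError(
            f"4th dimension {nv} != timing.n_volumes {timing.n_volumes}"
        )
    if nz != timing.n_slices:
        raise InvalidGeometryError(
            f"z dimension {nz} != timing.n_slices {timing.n_slices}"
        )
    if mask is not None and mask.shape != (nx, ny, nz):
        raise InvalidGeometryError("mask grid does not match the fMRI grid")
    if peaks.n_peaks < 10:
        raise InsufficientBeatsError(f"{peaks.n_peaks} peaks; need >= 10")

    vol_starts = (np.arange(nv - n_drop) + n_drop) * timing.tr
    idx_all, slice_all, even_all, odd_all, r2_all = [], [], [], [], []
    n_slices = timing.n_slices
    counts_e = counts_o = centers_s = centers_f = None

    for s in range(n_slices):
        t = vol_starts + timing.slice_offsets[s]
        samp, bins, par, rel, n_bins, lo_s = _bin_assignments(
            t, peaks, window, timing.slice_duration
        )
        if counts_e is None:
            counts_e = np.zeros((n_slices, n_bins))
            counts_o = np.zeros((n_slices, n_bins))
            centers_s = np.zeros((n_slices, n_bins))
            centers_f = np.zeros((n_slices, n_bins))
        raw = data[:, :, s, :].reshape(nx * ny, nv)
        in_mask = np.ones(nx * ny, dtype=bool)
        if mask is not None:
            in_mask = mask[:, :, s].reshape(nx * ny).astype(bool)
        pct = percent_modulation(raw, n_drop=n_drop)
        good = in_mask & np.isfinite(pct).all(axis=1)
        if not np.any(good):
            continue
        even, odd, ce, co, c_s, c_f = _binned_means(
            pct[good],
            samp,
            bins,
            par,
            rel,
            n_bins,
            lo_s,
            timing.slice_duration,
            peaks.cycle_estimate,
        )
        counts_e[s], counts_o[s] = ce, co
        centers_s[s], centers_f[s] = c_s, c_f
        valid = np.isfinite(even) & np.isfinite(odd)
        y = np.where(valid, even, 0.0)
        f = np.where(valid, odd, 0.0)
        ss_data = np.sum(y**2, axis=1)
        ss_resid = np.sum((y - f) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = 100.0 * (1.0 - ss_resid / ss_data)
        r2[(ss_data == 0) | (valid.sum(axis=1) < 2)] = np.nan
        flat = np.nonzero(good)[0]
        ii, jj = np.unravel_index(flat, (nx, ny))
        idx_all.append(np.column_stack([ii, jj, np.full(flat.size, s)]))
        slice_all.append(np.full(flat.size, s))
        even_all.append(even)
        odd_all.append(odd)
        r2_all.append(r2)

    if not idx_all:
        raise InvalidGeometryError("no usable voxels (all masked or background)")
    voxel_indices = np.concatenate(idx_all)
    r2_flat = np.concatenate(r2_all)
    r2_map = np.full((nx, ny, nz), np.nan)
    r2_map[tuple(voxel_indices.T)] = r2_flat
    return AlignedVolume(
        voxel_indices=voxel_indices,
        voxel_slice=np.concatenate(slice_all),
        even=np.concatenate(even_all),
        odd=np.concatenate(odd_all),
        r2=r2_flat,
        counts_even=counts_e,
        counts_odd=counts_o,
        bin_centers_s=centers_s,
        bin_centers_frac=centers_f,
        r2_map=r2_map,
        cycle_estimate=peaks.cycle_estimate,
        window=window,
        affine=affine,
    )
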