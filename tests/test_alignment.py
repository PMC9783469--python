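"""Cardiac alignment: percent modulation, slice timing, binning, reliability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainbeat as bb
from brainbeat.alignment import _bin_assignments
from brainbeat.errors import (
    BrainbeatError,
    InvalidGeometryError,
    TraceTooShortError,
)


class TestPercentModulation:
    def test_constant_series_maps_to_zero(self):
        out = bb.percent_modulation(np.full(10, 500.0))
        assert out.shape == (7,)
        assert np.allclose(out, 0.0)

    def test_zero_mean_and_zero_slope(self):
        x = np.array([100.0, 100, 100, 100, 102, 98, 100])
        out = bb.percent_modulation(x, n_drop=3)
        assert out.shape == (4,)
        assert out.sum() == pytest.approx(0.0, abs=1e-9)
        # closed-form least-squares slope of the residual is zero
        t = np.arange(out.size)
        slope = np.polyfit(t, out, 1)[0]
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_hand_case_values(self):
        # kept volumes 102, 98, 100: percent = [2, -2, 0] around mean 100,
        # minus LS line through them
        x = np.array([1.0, 1, 1, 102, 98, 100])
        out = bb.percent_modulation(x, n_drop=3)
        pct = 100 * (np.array([102.0, 98, 100]) - 100) / 100
        t = np.arange(3)
        coef = np.polyfit(t, pct, 1)
        assert np.allclose(out, pct - np.polyval(coef, t), atol=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(TraceTooShortError):
            bb.percent_modulation(np.ones(3), n_drop=3)

    def test_background_voxel_masked_not_raised(self):
        assert bb.percent_modulation(np.zeros(10)) is None
        out2d = bb.percent_modulation(np.vstack([np.zeros(10), np.full(10, 10.0)]))
        assert np.isnan(out2d[0]).all() and np.isfinite(out2d[1]).all()


class TestSliceTiming:
    def test_sms_protocol_five_groups(self):
        t = bb.slice_offsets_sms(0.25, 40, 8, 878)
        assert t.slice_duration == pytest.approx(0.05)
        assert np.allclose(np.unique(t.slice_offsets), [0, 0.05, 0.10, 0.15, 0.20])
        # simultaneous slices share an offset: 8 slices per group
        assert all(np.sum(t.slice_offsets == o) == 8 for o in np.unique(t.slice_offsets))

    def test_sequential_resting_state(self):
        t = bb.slice_offsets_sms(2.0, 45, 1, 240)
        assert t.slice_offsets.size == 45
        assert np.allclose(np.diff(np.sort(t.slice_offsets)), 2.0 / 45)
        assert t.slice_duration == pytest.approx(0.0444, abs=1e-3)

    def test_all_simultaneous(self):
        t = bb.slice_offsets_sms(1.0, 16, 16, 100)
        assert np.all(t.slice_offsets == 0)

    def test_indivisible_raises(self):
        with pytest.raises(InvalidGeometryError):
            bb.slice_offsets_sms(0.25, 40, 7, 878)

    def test_bids_slice_timing_round(self):
        offsets = [0.0, 0.05, 0.10, 0.15, 0.20] * 8
        t = bb.timing_from_bids(0.25, offsets, 878)
        assert t.slice_duration == pytest.approx(0.05)


class TestReliabilityR2:
    @pytest.mark.parametrize(
        "even,odd,expected",
        [
            ([1.0, 2.0, -3.0], [1.0, 2.0, -3.0], 100.0),  # identical halves
            ([3.0, 4.0], [0.0, 0.0], 0.0),  # odd flat: SSres == SSdata
            ([3.0, 4.0], [3.0, 0.0], 36.0),  # 100*(1 - 16/25)
            ([1.0, 2.0], [-1.0, -2.0], -300.0),  # anti-correlated halves
        ],
    )
    def test_formula_identities(self, even, odd, expected):
        assert bb.reliability_r2(even, odd) == pytest.approx(expected, abs=1e-12)

    def test_undefined_when_even_all_zero(self):
        assert np.isnan(bb.reliability_r2([0.0, 0.0], [1.0, 2.0]))

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=50),
    )
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        y, f = rng.normal(size=12), rng.normal(size=12)
        assert bb.reliability_r2(scale * y, scale * f) == pytest.approx(
            bb.reliability_r2(y, f), rel=1e-9
        )


def _periodic_peaks(n=218):
    return bb.PeakSeries(np.arange(1.0, n + 1.0), 1.0)


class TestAlignToPeaks:
    @pytest.mark.parametrize("slc", [0, 7, 13, 39])
    def test_cosine_phase_oracle_per_slice_group(self, slc):
        """Noiseless cos(2πt) locked to 1 s beats: the binned waveform must
        equal the cosine at the (empirical) bin centers for any slice offset."""
        timing = bb.slice_offsets_sms(0.25, 40, 8, 878)
        t = (np.arange(875) + 3) * 0.25 + timing.slice_offsets[slc]
        vox = bb.VoxelSeries(np.cos(2 * np.pi * t), t)
        resp = bb.align_to_peaks(vox, _periodic_peaks(), timing)
        ok = np.isfinite(resp.even_mean)
        err = np.abs(resp.even_mean[ok] - np.cos(2 * np.pi * resp.bin_centers_s[ok]))
        assert err.max() < 0.005
        assert resp.r2 > 99

    def test_twenty_bins_per_cycle(self):
        timing = bb.slice_offsets_sms(0.25, 40, 8, 878)
        assert int(round(1.0 / timing.slice_duration)) == 20
        # and the epoch window [-0.5, 1.0) at a 1 s cycle holds 30 such bins
        t = (np.arange(875) + 3) * 0.25
        resp = bb.align_to_peaks(bb.VoxelSeries(np.cos(2 * np.pi * t), t), _periodic_peaks(), timing)
        in_cycle = (resp.bin_centers_frac >= 0) & (resp.bin_centers_frac < 1.0)
        assert in_cycle.sum() == 20

    def test_count_conservation_and_max_two_assignments(self):
        peaks = _periodic_peaks()
        t = (np.arange(875) + 3) * 0.25
        samp, bins, par, rel, n_bins, lo = _bin_assignments(t, peaks, (-0.5, 1.0), 0.05)
        counts = np.bincount(samp, minlength=t.size)
        assert counts.max() <= 2
        timing = bb.slice_offsets_sms(0.25, 40, 8, 878)
        resp = bb.align_to_peaks(bb.VoxelSeries(np.zeros_like(t) + 0.0, t), peaks, timing)
        assert resp.counts_even.sum() + resp.counts_odd.sum() == samp.size

    def test_insufficient_beats(self):
        timing = bb.slice_offsets_sms(0.25, 40, 8, 878)
        peaks = bb.PeakSeries(np.arange(1.0, 6.0), 1.0)
        t = (np.arange(875) + 3) * 0.25
        with pytest.raises(BrainbeatError):
            bb.align_to_peaks(bb.VoxelSeries(np.cos(t), t), peaks, timing)


class TestNullDistribution:
    def test_noise_voxels_fall_below_reliability_threshold(self):
        """Monte-Carlo null: for pure noise the even and odd halves are
        independent, E[Σ(y−f)²] = 2·E[Σy²], so the zero-referenced R²
        centers at −100 — far below any reliability threshold."""
        cfg = bb.SimConfig(seed=9, grid=(6, 6, 40))
        trace, truth0 = bb.generate_ppg(cfg)
        class_map = np.zeros(cfg.grid, dtype=np.int16)  # all null
        img, _ = bb.generate_fmri(cfg, truth0, class_map=class_map)
        peaks = bb.detect_peaks(trace)
        aligned = bb.align_volume(img, peaks, cfg.timing)
        r2 = aligned.r2[np.isfinite(aligned.r2)]
        assert r2.size >= 1000
        assert np.mean(r2 < 30) >= 0.99
        assert np.median(r2) == pytest.approx(-100.0, abs=20.0)


class TestEvenOddConvention:
    def test_parity_swap_changes_reliable_r2_little(self):
        """Dropping the first beat flips the parity convention; on ~430
        beats of template-locked signal the R² of a reliable voxel moves by
        less than 5 points."""
        rng = np.random.default_rng(3)
        timing = bb.slice_offsets_sms(0.25, 40, 8, 1756)
        n_beats = 436
        beats = np.cumsum(1.0 + 0.03 * np.sin(0.07 * np.arange(n_beats)) + rng.normal(0, 0.01, n_beats))
        peaks = bb.PeakSeries(beats, 1.0)
        w = bb.waveform_template("artery")
        t = (np.arange(1753) + 3) * 0.25
        prev = np.clip(np.searchsorted(beats, t, side="right") - 1, 0, beats.size - 1)
        sig = w((t - beats[prev]) / 1.0) + rng.normal(0, 0.5, t.size)
        vox = bb.VoxelSeries(sig, t)
        r2_a = bb.align_to_peaks(vox, peaks, timing).r2
        r2_b = bb.align_to_peaks(vox, bb.PeakSeries(beats[1:], 1.0), timing).r2
        assert r2_a > 50
        assert abs(r2_a - r2_b) < 5


class TestAlignVolume:
    def test_template_voxels_reliable_null_voxels_not(self, sms_dataset):
        aligned = sms_dataset["aligned"]
        cls = sms_dataset["truth"].class_map[tuple(aligned.voxel_indices.T)]
        r2 = aligned.r2
        assert np.median(r2[cls > 0]) > 50
        assert np.mean(r2[cls == 0] < 30) >= 0.99

    def test_r2_map_matches_flat_values(self, sms_dataset):
        aligned = sms_dataset["aligned"]
        vals = aligned.r2_map[tuple(aligned.voxel_indices.T)]
        assert np.allclose(vals, aligned.r2, equal_nan=True)

    def test_all_zero_volume_fully_masked(self):
        timing = bb.slice_offsets_sms(0.25, 4, 2, 100)
        peaks = bb.PeakSeries(np.arange(1.0, 25.0), 1.0)
        with pytest.raises(BrainbeatError):
            bb.align_volume(np.zeros((2, 2, 4, 100)), peaks, timing)

    def test_geometry_mismatch(self):
        timing = bb.slice_offsets_sms(0.25, 4, 2, 100)
        peaks = bb.PeakSeries(np.arange(1.0, 25.0), 1.0)
        with pytest.raises(InvalidGeometryError):
            bb.align_volume(np.ones((2, 2, 4, 99)), peaks, timing)

    def test_resting_state_variant_recovers_extremum_signs(self):
        """TR 2 s sequential acquisition still recovers artery dips and CSF
        bumps with the correct sign."""
        cfg = bb.SimConfig(seed=4, grid=(4, 4, 45)).resting_state()
        trace, truth0 = bb.generate_ppg(cfg)
        img, truth = bb.generate_fmri(cfg, truth0)
        peaks = bb.detect_peaks(trace)
        aligned = bb.align_volume(img, peaks, cfg.timing)
        cls = truth.class_map[tuple(aligned.voxel_indices.T)]
        for code, name, sign in [(1, "artery", -1), (3, "csf", +1)]:
            t0 = truth.templates[name].extremum_frac
            sel = (cls == code) & (aligned.r2 > 50)
            assert sel.sum() > 10
            hits = n = 0
            for i in np.nonzero(sel)[0]:
                s = aligned.voxel_slice[i]
                y = aligned.odd[i]
                fin = np.isfinite(y)
                # deflection at the transient's phase, relative to the
                # waveform's own phase mean (a 2 s TR samples the cycle
                # sparsely, so the removed temporal mean includes part of
                # the transient and absolute sign is not meaningful)
                d = np.abs(aligned.bin_centers_frac[s] - t0)
                d[~fin] = np.inf
                if d.min() > 0.1:
                    continue  # extremum phase not covered for this slice
                yc = y - np.nanmean(y)
                hits += np.sign(yc[np.argmin(d)]) == sign
                n += 1
            assert n > 10
            assert hits / n > 0.9
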