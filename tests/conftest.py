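"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import brainbeat as bb


@pytest.fixture(scope="session")
def sms_dataset():
    """Full-size simulated SMS run (8×8×40, TR 0.25 s, 878 volumes, 60 bpm,
    10 ms jitter) with detected peaks and aligned waveforms; shared across
    tests because generation + alignment is the expensive part."""
    cfg = bb.SimConfig(seed=1)
    trace, truth0 = bb.generate_ppg(cfg)
    img, truth = bb.generate_fmri(cfg, truth0)
    peaks = bb.detect_peaks(trace)
    aligned = bb.align_volume(img, peaks, cfg.timing)
    return {
        "cfg": cfg,
        "trace": trace,
        "img": img,
        "truth": truth,
        "peaks": peaks,
        "aligned": aligned,
    }


@pytest.fixture(scope="session")
def resampled_waveforms(sms_dataset):
    """Odd/even waveforms of the shared run on the standard grid
    (mean-preserving resampling, as on the pipeline's timing path)."""
    aligned = sms_dataset["aligned"]
    grid = bb.cycle_fraction_grid()
    n = aligned.n_voxels
    odd = np.full((n, grid.size), np.nan)
    even = np.full((n, grid.size), np.nan)
    for i in range(n):
        s = aligned.voxel_slice[i]
        o = bb.resample_to_cycle(
            bin_centers_frac=aligned.bin_centers_frac[s],
            values=aligned.odd[i],
            grid=grid,
            method="mean-preserving",
        )
        e = bb.resample_to_cycle(
            bin_centers_frac=aligned.bin_centers_frac[s],
            values=aligned.even[i],
            grid=grid,
            method="mean-preserving",
        )
        if o is not None:
            odd[i] = o
        if e is not None:
            even[i] = e
    return {"grid": grid, "odd": odd, "even": even}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
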