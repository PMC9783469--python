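"""Ground-truth simulator: PPG traces and SMS-timed 4-D volumes.

The generator emits everything the pipeline consumes — a quasi-periodic
~1 Hz pulse-oximeter trace with beat-to-beat Gaussian jitter, and a 4-D
volume whose voxels carry cardiac-locked waveform templates evaluated at
each sample's true phase given its slice's acquisition offset — plus the
generating truth (beat times, per-voxel class and extremum time), so every
pipeline stage can be tested for parameter recovery without any download.

Voxel classes mimic the compartments seen in vivo: artery-like voxels dip
sharply ~0.15 cycle before the PPG peak (blood reaches the brain before the
finger), vein-like voxels dip at the peak, CSF-like voxels peak just after
it (displaced by arterial inflow in the closed cranium), and null voxels
carry only noise and drift.  Transients are skewed (fast onset, slow
return), as pulse-pressure waveforms are.  Waveforms are imposed directly
in percent units; the biophysical T1-weighting of the contrast is not
modeled mechanistically, but a steady-state spoiled gradient-echo signal
utility is provided to compare sequence sensitivities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .alignment import AcquisitionTiming, slice_offsets_sms
from .errors import BrainbeatError, InvalidGeometryError, InvalidParameterError
from .physio import PhysioTrace, write_bids_physio

__all__ = [
    "TemplateParams",
    "DEFAULT_TEMPLATES",
    "SimConfig",
    "GroundTruth",
    "waveform_template",
    "generate_ppg",
    "generate_fmri",
    "default_class_map",
    "write_simulated_dataset",
    "gradient_echo_signal",
    "rank_two_dataset",
]

CLASS_CODES = {"null": 0, "artery": 1, "vein": 2, "csf": 3}


@dataclass(frozen=True)
class TemplateParams:
    """Shape parameters of one class's cardiac-locked transient.

    ``extremum_frac`` is the cycle fraction of the extremum relative to the
    PPG peak; ``sign`` −1 for a dip (blood) or +1 for a bump (CSF);
    ``amplitude`` in percent modulation; onset/return widths (cycle
    fractions) encode the fast-onset/slow-return asymmetry.
    """

    extremum_frac: float
    amplitude: float
    sign: int
    onset_width: float = 0.06
    return_width: float = 0.18


DEFAULT_TEMPLATES: dict[str, TemplateParams] = {
    "artery": TemplateParams(extremum_frac=-0.15, amplitude=1.5, sign=-1),
    "vein": TemplateParams(extremum_frac=0.0, amplitude=1.0, sign=-1),
    "csf": TemplateParams(extremum_frac=0.05, amplitude=1.0, sign=+1),
}


def waveform_template(class_name: str, params: TemplateParams | None = None):
    """Return the class's waveform as a 1-cycle-periodic function of cycle
    fraction (percent modulation).  The null class returns identically 0."""
    if class_name == "null":
        return lambda frac: np.zeros_like(np.asarray(frac, dtype=float))
    if params is None:
        try:
            params = DEFAULT_TEMPLATES[class_name]
        except KeyError:
            raise InvalidParameterError(f"unknown voxel class {class_name!r}") from None

    def wave(frac):
        frac = np.asarray(frac, dtype=float)
        d = frac - params.extremum_frac
        d = d - np.round(d)  # wrap to [-0.5, 0.5): periodic in the cycle
        w = np.where(d < 0, params.onset_width, params.return_width)
        return params.sign * params.amplitude * np.exp(-0.5 * (d / w) ** 2)

    return wave


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults follow the fast SMS protocol: heart rate 60 bpm with 10 ms
    beat-to-beat jitter, 220 s of 100 Hz PPG, 8×8 in-plane × 40 slices
    acquired as 5 simultaneous groups of 8 (TR 250 ms, 50 ms per group),
    878 volumes.  ``noise_sd`` (percent) is thermal noise per sample;
    ``drift_percent`` a linear drift over the scan.

    ``hr_drift_frac``/``hr_drift_period`` impose a slow sinusoidal
    modulation of the heartbeat period (default ±3% over ~90 s), the
    gradual heart-rate meander every resting subject shows.  It adds
    almost nothing to beat-to-beat RMSSD but sweeps each slice's sampling
    phase across the cardiac cycle — without it, a heart rate commensurate
    with the TR (1 s vs 0.25 s) leaves the peak-relative bins covered only
    by the jitter random walk, a degenerate sampling no real recording has.
    """

    heart_rate: float = 60.0
    jitter_sd: float = 0.010
    hr_drift_frac: float = 0.03
    hr_drift_period: float = 90.0
    duration: float = 220.0
    physio_fs: float = 100.0
    physio_start_time: float = 0.0
    ppg_noise_sd: float = 0.05
    grid: tuple[int, int, int] = (8, 8, 40)
    timing: AcquisitionTiming = field(
        default_factory=lambda: slice_offsets_sms(0.25, 40, 8, 878)
    )
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    noise_sd: float = 0.5
    drift_percent: float = 0.5
    seed: int = 0

    @property
    def cycle(self) -> float:
        return 60.0 / self.heart_rate

    def resting_state(self) -> "SimConfig":
        """The slow sequential-acquisition variant (TR 2 s, 45 slices,
        44.4 ms per slice, 240 volumes, 480 s)."""
        return replace(
            self,
            grid=(self.grid[0], self.grid[1], 45),
            timing=slice_offsets_sms(2.0, 45, 1, 240),
            duration=480.0,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Generating truth emitted alongside the data."""

    peak_times: np.ndarray
    cycle: float
    class_map: np.ndarray | None = None
    templates: dict | None = None

    def class_of(self, index: tuple[int, int, int]) -> str:
        code = int(self.class_map[index])
        return {v: k for k, v in CLASS_CODES.items()}[code]

    def extremum_frac(self, class_name: str) -> float:
        return self.templates[class_name].extremum_frac

    def extremum_sign(self, class_name: str) -> int:
        return self.templates[class_name].sign


def _pulse_shape(dt: np.ndarray) -> np.ndarray:
    """Stereotyped PPG pulse: sharp systolic peak, slow diastolic run-off,
    dicrotic bump.  The apex itself is symmetric (asymmetry lives in the
    run-off terms), so the zero-phase 5 Hz low-pass used before peak
    detection moves the apex by only ~2 ms."""
    apex = np.exp(-0.5 * (dt / 0.06) ** 2)
    runoff = 0.25 * np.exp(-0.5 * ((dt - 0.28) / 0.12) ** 2)
    dicrotic = 0.15 * np.exp(-0.5 * ((dt - 0.42) / 0.07) ** 2)
    return apex + runoff + dicrotic


def generate_ppg(cfg: SimConfig) -> tuple[PhysioTrace, GroundTruth]:
    """Simulate the pulse-oximeter trace; returns (trace, truth).

    Beat times accumulate nominal-cycle + Gaussian-jitter intervals; each
    beat renders the stereotyped pulse; additive Gaussian noise on top.
    """
    if cfg.duration < 10 * cfg.cycle:
        raise InvalidParameterError("duration must cover at least 10 beats")
    rng = np.random.default_rng(cfg.seed)
    n_beats = int(np.ceil(cfg.duration / cfg.cycle * 1.1)) + 2
    phase0 = rng.uniform(0.0, 2 * np.pi)
    k = np.arange(n_beats)
    drift = cfg.hr_drift_frac * np.sin(
        2 * np.pi * k * cfg.cycle / cfg.hr_drift_period + phase0
    )
    intervals = cfg.cycle * (1.0 + drift) + rng.normal(0.0, cfg.jitter_sd, n_beats)
    if np.any(intervals <= 0.4 * cfg.cycle):
        raise BrainbeatError("jitter so large that beats overlap")
    beats = np.cumsum(intervals)
    beats = beats[beats < cfg.duration - 0.5]
    t = cfg.physio_start_time + np.arange(int(cfg.duration * cfg.physio_fs)) / cfg.physio_fs
    x = np.zeros_like(t)
    for b in beats:
        lo = np.searchsorted(t, b - 0.6)
        hi = np.searchsorted(t, b + 0.7)
        x[lo:hi] += _pulse_shape(t[lo:hi] - b)
    x += rng.normal(0.0, cfg.ppg_noise_sd, x.size)
    trace = PhysioTrace(x, cfg.physio_fs, cfg.physio_start_time, "ppg")
    return trace, GroundTruth(peak_times=beats, cycle=cfg.cycle)


def default_class_map(
    grid: tuple[int, int, int],
    seed: int = 0,
    fractions: dict[str, float] | None = None,
) -> np.ndarray:
    """Random voxel-class assignment (codes: 0 null, 1 artery, 2 vein, 3 csf).

    Default composition: 15% artery, 15% vein, 15% CSF, 55% null — most of
    the volume, as in vivo, carries no reliable cardiac signal.
    """
    fractions = fractions or {"artery": 0.15, "vein": 0.15, "csf": 0.15}
    rng = np.random.default_rng(seed)
    u = rng.random(grid)
    cm = np.zeros(grid, dtype=np.int16)
    lo = 0.0
    for name in ("artery", "vein", "csf"):
        hi = lo + fractions[name]
        cm[(u >= lo) & (u < hi)] = CLASS_CODES[name]
        lo = hi
    return cm


def generate_fmri(
    cfg: SimConfig,
    truth: GroundTruth,
    class_map: np.ndarray | None = None,
) -> tuple[nib.Nifti1Image, GroundTruth]:
    """Simulate the 4-D run locked to the true beat times.

    Each voxel's sample at volume v in slice s is its class template
    evaluated at phase (t − preceding true peak)/cycle with
    t = v·TR + slice_offset(s), on a baseline of 100, plus linear drift and
    Gaussian noise.  Returns the NIfTI image (with slice-timing metadata in
    the sidecar written by :func:`write_simulated_dataset`) and the truth
    extended with the class map.
    """
    nx, ny, nz = cfg.grid
    timing = cfg.timing
    if nz != timing.n_slices:
        raise InvalidGeometryError(
            f"grid z={nz} does not match timing.n_slices={timing.n_slices}"
        )
    if class_map is None:
        class_map = default_class_map(cfg.grid, seed=cfg.seed + 1)
    if class_map.shape != cfg.grid:
        raise InvalidGeometryError("class_map shape does not match grid")
    rng = np.random.default_rng(cfg.seed + 2)
    nv = timing.n_volumes
    scan_len = nv * timing.tr
    beats = truth.peak_times
    waves = {name: waveform_template(name, cfg.templates.get(name)) for name in CLASS_CODES}
    data = np.empty((nx, ny, nz, nv), dtype=np.float64)
    vol_t = np.arange(nv) * timing.tr
    for s in range(nz):
        t = vol_t + timing.slice_offsets[s]
        prev = np.clip(np.searchsorted(beats, t, side="right") - 1, 0, beats.size - 1)
        phase = (t - beats[prev]) / cfg.cycle
        drift = cfg.drift_percent * (t / scan_len)
        for name, code in CLASS_CODES.items():
            sel = class_map[:, :, s] == code
            if not np.any(sel):
                continue
            base = 100.0 + waves[name](phase) + drift
            data[:, :, s, :][sel] = base
    data += rng.normal(0.0, cfg.noise_sd, data.shape)
    img = nib.Nifti1Image(data.astype(np.float32), np.diag([4.0, 4.0, 4.0, 1.0]))
    img.header.set_zooms((4.0, 4.0, 4.0, timing.tr))
    full = GroundTruth(
        peak_times=beats,
        cycle=cfg.cycle,
        class_map=class_map,
        templates={k: (cfg.templates.get(k) or DEFAULT_TEMPLATES[k]) for k in DEFAULT_TEMPLATES},
    )
    return img, full


def write_simulated_dataset(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write a miniature BIDS-like dataset and return its file paths.

    Layout: ``func/sim_bold.nii.gz`` + ``func/sim_bold.json`` (RepetitionTime,
    SliceTiming), ``func/sim_physio.tsv.gz`` + sidecar, ``labels.nii.gz``
    (class map) and ``truth.json`` (beat times, per-class template params).
    """
    outdir = Path(outdir)
    (outdir / "func").mkdir(parents=True, exist_ok=True)
    trace, truth0 = generate_ppg(cfg)
    img, truth = generate_fmri(cfg, truth0)
    paths = {
        "bold": outdir / "func" / "sim_bold.nii.gz",
        "bold_json": outdir / "func" / "sim_bold.json",
        "physio": outdir / "func" / "sim_physio.tsv.gz",
        "labels": outdir / "labels.nii.gz",
        "truth": outdir / "truth.json",
    }
    nib.save(img, str(paths["bold"]))
    paths["bold_json"].write_text(
        json.dumps(
            {
                "RepetitionTime": cfg.timing.tr,
                "SliceTiming": list(cfg.timing.slice_offsets),
                "NumberOfVolumes": cfg.timing.n_volumes,
            },
            indent=2,
        )
    )
    write_bids_physio(trace, paths["physio"])
    nib.save(
        nib.Nifti1Image(truth.class_map.astype(np.int16), np.diag([4.0, 4.0, 4.0, 1.0])),
        str(paths["labels"]),
    )
    paths["truth"].write_text(
        json.dumps(
            {
                "peak_times": list(truth.peak_times),
                "cycle": truth.cycle,
                "class_codes": CLASS_CODES,
                "templates": {
                    k: {
                        "extremum_frac": v.extremum_frac,
                        "amplitude": v.amplitude,
                        "sign": v.sign,
                        "onset_width": v.onset_width,
                        "return_width": v.return_width,
                    }
                    for k, v in truth.templates.items()
                },
                "seed": cfg.seed,
            },
            indent=2,
        )
    )
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Spoiled gradient-echo signal utility


@dataclass(frozen=True)
class GradientEchoSignal:
    """Steady-state spoiled gradient-echo signal and parameter sensitivities."""

    signal: float
    sens_t1: float  # |∂S/∂T1|
    sens_t2star: float  # |∂S/∂T2*|


def gradient_echo_signal(
    m0: float, t1: float, t2star: float, tr: float, te: float, flip_deg: float
) -> GradientEchoSignal:
    """S = M0·sin α·(1−E1)/(1−cos α·E1)·exp(−TE/T2*), E1 = exp(−TR/T1).

    Sensitivities are the analytic |∂S/∂T1| and |∂S/∂T2*|; used to compare
    the T1- vs T2*-weighting of a fast SMS protocol (short TR/TE, low flip)
    against a conventional resting-state protocol.
    """
    if min(m0, t1, t2star, tr, te if te > 0 else 1.0) <= 0 or te < 0:
        raise InvalidParameterError("m0, t1, t2star, tr must be > 0 and te >= 0")
    if not 0 < flip_deg < 180:
        raise InvalidParameterError("flip angle must be in (0, 180) degrees")
    alpha = np.deg2rad(flip_deg)
    e1 = np.exp(-tr / t1)
    decay = np.exp(-te / t2star)
    denom = 1.0 - np.cos(alpha) * e1
    s = m0 * np.sin(alpha) * (1.0 - e1) / denom * decay
    # dS/dT1 via dE1/dT1 = E1·TR/T1²; d/dE1[(1−E1)/(1−cE1)] = (c−1)/(1−cE1)²
    ds_de1 = m0 * np.sin(alpha) * decay * (np.cos(alpha) - 1.0) / denom**2
    sens_t1 = abs(ds_de1 * e1 * tr / t1**2)
    sens_t2 = abs(s * te / t2star**2)
    return GradientEchoSignal(float(s), float(sens_t1), float(sens_t2))


# ---------------------------------------------------------------------------
# Rank-2 waveform ensemble with noise calibrated to a target reliability


def _orthonormal_pair(grid: np.ndarray) -> np.ndarray:
    """Two fixed orthonormal skewed-transient time courses on the grid."""
    c1 = waveform_template("artery")(grid)
    c2 = waveform_template("csf")(grid)
    c1 = c1 / np.linalg.norm(c1)
    c2 = c2 - c1 * np.dot(c1, c2)
    c2 = c2 / np.linalg.norm(c2)
    return np.column_stack([c1, c2])


def rank_two_dataset(
    n_voxels: int,
    grid: np.ndarray,
    target_r2: float = 70.0,
    seed: int = 0,
) -> dict:
    """Even/odd waveform copies spanned by two components, noise tuned so
    the median zero-referenced R² between copies hits ``target_r2``.

    Per-voxel waveforms are random weighted sums of two fixed orthonormal
    skewed transients; even and odd copies add independent Gaussian noise
    whose scale is found by bisection on the realized median R².  Returns
    the copies, the truth, the components, the betas and the noise scale.
    """
    rng = np.random.default_rng(seed)
    C = _orthonormal_pair(np.asarray(grid))
    betas = rng.normal(0.0, 1.0, (n_voxels, 2))
    truth = betas @ C.T
    n1 = rng.normal(0.0, 1.0, truth.shape)
    n2 = rng.normal(0.0, 1.0, truth.shape)

    def median_r2(sigma: float) -> float:
        y = truth + sigma * n1
        f = truth + sigma * n2
        ss_d = np.sum(y**2, axis=1)
        ss_r = np.sum((y - f) ** 2, axis=1)
        return float(np.median(100.0 * (1.0 - ss_r / ss_d)))

    lo, hi = 1e-9, 10.0 * float(np.median(np.linalg.norm(truth, axis=1))) / np.sqrt(len(grid))
    while median_r2(hi) > target_r2:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if median_r2(mid) > target_r2:
            lo = mid
        else:
            hi = mid
    sigma = 0.5 * (lo + hi)
    return {
        "even": truth + sigma * n1,
        "odd": truth + sigma * n2,
        "truth": truth,
        "components": C,
        "betas": betas,
        "noise_sd": sigma,
        "median_r2": median_r2(sigma),
    }
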