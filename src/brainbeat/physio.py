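"""Physiological signal handling: PPG filtering, heartbeat peak detection, HRV.

The photoplethysmography (PPG) signal recorded at the fingertip during the
scan marks systolic blood arrival; its peaks define time zero for every
cardiac-aligned analysis downstream.  This module reads BIDS-style physio
recordings, detects the heartbeat peaks and quantifies ultrashort-window
heart-rate variability (RMSSD), which determines whether beat-to-beat timing
is stable enough (relative to one slice-acquisition window) for pooled
cardiac averaging.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    CycleNotFoundError,
    InsufficientBeatsError,
    InvalidParameterError,
    TraceTooShortError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhysioTrace",
    "PeakSeries",
    "HrvReport",
    "lowpass_filter",
    "estimate_cycle",
    "detect_peaks",
    "rmssd_hrv",
    "read_bids_physio",
    "write_peaks_tsv",
    "write_hrv_json",
]


@dataclass(frozen=True)
class PhysioTrace:
    """A uniformly sampled physiological signal.

    Parameters
    ----------
    samples
        Signal amplitudes (arbitrary units).
    sampling_rate
        Sampling frequency in Hz (> 0).
    start_time
        Time of sample 0 in seconds on the fMRI clock (time of the first
        fMRI volume = 0).  May be negative: physio recording typically
        starts before the scan.
    channel
        One of ``"ppg"``, ``"ecg"``, ``"respiration"``.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    channel: str = "ppg"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("samples must be finite")
        if self.channel not in ("ppg", "ecg", "respiration"):
            raise InvalidParameterError(f"unknown channel {self.channel!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times on the fMRI clock."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class PeakSeries:
    """Detected heartbeat peak times on the fMRI clock.

    ``cycle_estimate`` is the autocorrelation-derived heartbeat period used
    both for the minimum-distance constraint at detection time and for
    converting peak-relative time to cycle fraction downstream.
    """

    peak_times: np.ndarray
    cycle_estimate: float

    def __post_init__(self):
        pt = np.asarray(self.peak_times, dtype=float)
        object.__setattr__(self, "peak_times", pt)
        if pt.ndim != 1 or pt.size < 2:
            raise InsufficientBeatsError("need at least 2 peaks")
        if np.any(np.diff(pt) <= 0):
            raise InvalidParameterError("peak_times must be strictly increasing")
        if self.cycle_estimate <= 0:
            raise InvalidParameterError("cycle_estimate must be > 0")

    @property
    def n_peaks(self) -> int:
        return self.peak_times.size

    @property
    def inter_beat_intervals(self) -> np.ndarray:
        """Successive peak spacings in seconds (length ``n_peaks - 1``)."""
        return np.diff(self.peak_times)

    @property
    def mean_heart_rate(self) -> float:
        """Mean heart rate in beats per minute."""
        return 60.0 / float(np.mean(self.inter_beat_intervals))


@dataclass(frozen=True)
class HrvReport:
    """RMSSD heart-rate variability over contiguous short windows.

    ``rmssd_per_window`` holds one value (ms) per window; windows with too
    few beats are NaN and excluded from ``max_rmssd``.  ``passes_threshold``
    is True when the worst window stays below ``threshold_ms`` — the check
    that beat jitter is smaller than one slice-acquisition window, so no
    per-beat time warping is needed before pooling.
    """

    window_length: float
    rmssd_per_window: np.ndarray
    max_rmssd: float
    threshold_ms: float
    passes_threshold: bool


def lowpass_filter(trace: PhysioTrace, cutoff: float = 5.0, order: int = 3) -> PhysioTrace:
    """Zero-phase Butterworth low-pass filter (applied forward and backward).

    Defaults to 5 Hz, third order; run in two directions the effective
    magnitude response is the squared Butterworth magnitude and the net
    phase shift is zero, so peak times are preserved.
    """
    if order < 1:
        raise InvalidParameterError("order must be >= 1")
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise InvalidParameterError(
            f"cutoff must lie in (0, Nyquist={nyquist:g} Hz); got {cutoff:g}"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=trace.sampling_rate)
    padlen = 3 * max(len(a), len(b))  # filtfilt default
    if trace.n_samples <= padlen:
        raise TraceTooShortError(
            f"trace has {trace.n_samples} samples; filter warm-up needs > {padlen}"
        )
    filtered = signal.filtfilt(b, a, trace.samples)
    return PhysioTrace(filtered, trace.sampling_rate, trace.start_time, trace.channel)


def estimate_cycle(
    trace: PhysioTrace,
    hr_range: tuple[float, float] = (40.0, 150.0),
    min_autocorr: float = 0.2,
) -> float:
    """Heartbeat period (s) from the dominant autocorrelation peak.

    The search is restricted to lags inside the physiological heart-rate
    band ``hr_range`` (bpm), which excludes the trivial zero-lag peak and
    sub-/super-harmonics.  The winning peak must reach ``min_autocorr`` of
    the zero-lag value; white noise has no such peak and raises
    :class:`CycleNotFoundError`.
    """
    min_bpm, max_bpm = hr_range
    if not 0 < min_bpm < max_bpm:
        raise InvalidParameterError("require 0 < min_bpm < max_bpm")
    fs = trace.sampling_rate
    lag_lo = int(round(60.0 / max_bpm * fs))
    lag_hi = int(round(60.0 / min_bpm * fs))
    if trace.duration < 4 * (60.0 / min_bpm):
        raise TraceTooShortError(
            "trace must span at least 4 maximum-plausible cycles"
        )
    x = trace.samples - trace.samples.mean()
    denom = float(np.dot(x, x))
    # guard against numerically-constant traces (filtfilt ripple ~1e-16)
    if denom <= (1e-10 * max(1.0, abs(trace.samples.mean()))) ** 2 * x.size:
        raise CycleNotFoundError("constant signal has no periodic structure")
    ac = signal.correlate(x, x, mode="full")[x.size - 1 :]
    ac = ac / denom
    peaks, _ = signal.find_peaks(ac)
    peaks = peaks[(peaks >= lag_lo) & (peaks <= lag_hi)]
    peaks = peaks[ac[peaks] >= min_autocorr]
    if peaks.size == 0:
        raise CycleNotFoundError(
            f"no autocorrelation peak in [{60.0 / max_bpm:.2f}, "
            f"{60.0 / min_bpm:.2f}] s with normalized value >= {min_autocorr}"
        )
    best = peaks[np.argmax(ac[peaks])]
    return best / fs


def detect_peaks(
    trace: PhysioTrace,
    cutoff: float = 5.0,
    order: int = 3,
    hr_range: tuple[float, float] = (40.0, 150.0),
    prominence_fraction: float = 0.25,
) -> PeakSeries:
    """Detect heartbeat peaks in a PPG trace.

    The trace is low-pass filtered (zero phase), the heartbeat period is
    estimated from the autocorrelation, and local maxima are picked with a
    minimum separation of 70% of that period.  A prominence floor of
    ``prominence_fraction`` of the filtered signal's interquartile range
    rejects dicrotic-notch secondary maxima.  Peak times are returned on
    the fMRI clock (``start_time`` applied).
    """
    if trace.channel != "ppg":
        raise InvalidParameterError(
            f"detect_peaks expects a PPG trace, got channel {trace.channel!r}"
        )
    filtered = lowpass_filter(trace, cutoff=cutoff, order=order)
    try:
        cycle = estimate_cycle(filtered, hr_range=hr_range)
    except CycleNotFoundError as exc:
        raise InsufficientBeatsError(
            "no heartbeat periodicity found in the PPG signal"
        ) from exc
    x = filtered.samples
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 1e-10 * max(1.0, abs(np.median(x))):
        raise InsufficientBeatsError("flat PPG signal")
    distance = max(1, int(0.7 * cycle * trace.sampling_rate))
    # the height floor rejects noise maxima in pulse-free stretches (e.g.
    # recording head/tail) that the prominence rule alone lets through
    idx, _ = signal.find_peaks(
        x,
        distance=distance,
        prominence=prominence_fraction * iqr,
        height=float(np.median(x) + prominence_fraction * iqr),
    )
    if idx.size < 3:
        raise InsufficientBeatsError(f"only {idx.size} peaks found (need >= 3)")
    peak_times = trace.start_time + idx / trace.sampling_rate
    return PeakSeries(peak_times=peak_times, cycle_estimate=cycle)


def rmssd_hrv(
    peaks: PeakSeries,
    window_length: float = 20.0,
    threshold: float = 50.0,
    trace_bounds: tuple[float, float] | None = None,
) -> HrvReport:
    """RMSSD heart-rate variability over contiguous non-overlapping windows.

    For each window, RMSSD = sqrt(mean(diff(IBI)^2)) in milliseconds, where
    the IBIs are the inter-beat intervals of the peaks falling inside the
    window.  Windows with fewer than 3 peaks are flagged missing (NaN) and
    excluded from the maximum.  ``threshold`` is in milliseconds; the
    default 50 ms equals one slice-acquisition window of the fast protocol.

    ``trace_bounds``, if given as (t_lo, t_hi) seconds, drops beats within
    half a cycle of the recording boundary (incomplete neighborhoods).
    """
    pt = peaks.peak_times
    if trace_bounds is not None:
        half = 0.5 * peaks.cycle_estimate
        pt = pt[(pt >= trace_bounds[0] + half) & (pt <= trace_bounds[1] - half)]
    if pt.size < 3:
        raise InsufficientBeatsError("need at least 3 peaks for RMSSD")
    t0 = pt[0]
    span = pt[-1] - t0
    n_windows = max(1, int(np.ceil(span / window_length - 1e-12)))
    rmssd = np.full(n_windows, np.nan)
    for w in range(n_windows):
        lo, hi = t0 + w * window_length, t0 + (w + 1) * window_length
        in_win = pt[(pt >= lo) & (pt < hi)]
        if in_win.size < 3:
            continue
        d = np.diff(np.diff(in_win))
        if d.size == 0:
            continue
        rmssd[w] = np.sqrt(np.mean(d**2)) * 1000.0
    if np.all(np.isnan(rmssd)):
        raise InsufficientBeatsError("no window contains enough peaks for RMSSD")
    max_rmssd = float(np.nanmax(rmssd))
    return HrvReport(
        window_length=window_length,
        rmssd_per_window=rmssd,
        max_rmssd=max_rmssd,
        threshold_ms=threshold,
        passes_threshold=bool(max_rmssd < threshold),
    )


# ---------------------------------------------------------------------------
# BIDS-style IO


def read_bids_physio(
    tsv_path: str | Path,
    sidecar_path: str | Path | None = None,
    column: str = "cardiac",
    channel: str = "ppg",
) -> PhysioTrace:
    """Read a BIDS physiological recording (``*_physio.tsv.gz`` + JSON sidecar).

    The sidecar provides ``SamplingFrequency``, ``StartTime`` and ``Columns``.
    ``column`` selects which column holds the pulse signal (BIDS convention:
    ``cardiac``).  A missing sidecar or missing ``StartTime`` yields
    start_time = 0 with a logged warning.
    """
    tsv_path = Path(tsv_path)
    if sidecar_path is None:
        name = tsv_path.name
        for suffix in (".tsv.gz", ".tsv"):
            if name.endswith(suffix):
                sidecar_path = tsv_path.with_name(name[: -len(suffix)] + ".json")
                break
    fs, start_time, columns = None, 0.0, None
    if sidecar_path is not None and Path(sidecar_path).exists():
        meta = json.loads(Path(sidecar_path).read_text())
        fs = meta.get("SamplingFrequency")
        columns = meta.get("Columns")
        if "StartTime" in meta:
            start_time = float(meta["StartTime"])
        else:
            logger.warning("sidecar %s has no StartTime; assuming 0", sidecar_path)
    else:
        logger.warning("no JSON sidecar for %s; assuming StartTime = 0", tsv_path)
    if fs is None:
        raise InvalidParameterError(
            f"SamplingFrequency not available for {tsv_path}; provide a sidecar"
        )
    df = pd.read_csv(tsv_path, sep="\t", header=None)
    if columns:
        df.columns = columns[: df.shape[1]]
        if column not in df.columns:
            raise InvalidParameterError(
                f"column {column!r} not in sidecar Columns {list(df.columns)}"
            )
        samples = df[column].to_numpy(dtype=float)
    else:
        samples = df.iloc[:, 0].to_numpy(dtype=float)
    return PhysioTrace(samples, float(fs), start_time, channel)


def write_peaks_tsv(peaks: PeakSeries, path: str | Path) -> None:
    """Write detected peaks as TSV (peak_index, peak_time_s, ibi_s)."""
    ibi = np.concatenate([[np.nan], peaks.inter_beat_intervals])
    pd.DataFrame(
        {
            "peak_index": np.arange(peaks.n_peaks),
            "peak_time_s": peaks.peak_times,
            "ibi_s": ibi,
        }
    ).to_csv(path, sep="\t", index=False, na_rep="n/a")


def write_hrv_json(report: HrvReport, path: str | Path) -> None:
    """Write the HRV report as JSON."""
    payload = {
        "window_length_s": report.window_length,
        "rmssd_ms_per_window": [
            None if np.isnan(v) else float(v) for v in report.rmssd_per_window
        ],
        "max_rmssd_ms": report.max_rmssd,
        "threshold_ms": report.threshold_ms,
        "passes_threshold": report.passes_threshold,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_bids_physio(
    trace: PhysioTrace, tsv_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write a trace in BIDS physio layout (gzipped TSV + JSON sidecar)."""
    tsv_path = Path(tsv_path)
    body = "\n".join(f"{v:.6f}" for v in trace.samples) + "\n"
    if tsv_path.suffix == ".gz":
        with gzip.open(tsv_path, "wt") as fh:
            fh.write(body)
        stem = tsv_path.name[: -len(".tsv.gz")]
    else:
        tsv_path.write_text(body)
        stem = tsv_path.stem
    if sidecar_path is None:
        sidecar_path = tsv_path.with_name(stem + ".json")
    Path(sidecar_path).write_text(
        json.dumps(
            {
                "SamplingFrequency": trace.sampling_rate,
                "StartTime": trace.start_time,
                "Columns": ["cardiac"],
            },
            indent=2,
        )
    )
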