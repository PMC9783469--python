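"""Region-of-interest aggregation and arterial-distance zone analysis.

Gray-matter regions can be grouped by which cerebral artery supplies them
(ACA / MCA / PCA) and how far along the arterial tree they sit (distance
level 1 = closest to the arterial input, 4 = furthest).  Pulsation amplitude
is expected to fall off with distance from the arterial input; this module
aggregates per-voxel cardiac-gated waveforms over user-supplied label
volumes and reports per-zone modulation amplitudes and their monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError, InvalidParameterError

__all__ = [
    "ZoneTable",
    "RoiWaveform",
    "read_zone_table",
    "starter_zone_table",
    "aggregate_roi",
    "aggregate_zones",
    "amplitude_gradient_test",
]

ARTERIES = ("ACA", "MCA", "PCA", "other")


@dataclass(frozen=True)
class ZoneTable:
    """Label → (region, artery, distance level) lookup.

    Columns: ``label`` (int, matching the label volume), ``region_name``,
    ``artery`` (ACA/MCA/PCA/other), ``distance_level`` (1–4, 1 = closest to
    the arterial input).
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        required = {"label", "region_name", "artery", "distance_level"}
        if not required.issubset(df.columns):
            raise InvalidParameterError(f"zone table needs columns {sorted(required)}")
        if df["label"].duplicated().any():
            raise InvalidParameterError("zone table labels must be unique")
        if not df["artery"].isin(ARTERIES).all():
            raise InvalidParameterError(f"artery must be one of {ARTERIES}")
        if not df["distance_level"].isin([1, 2, 3, 4]).all():
            raise InvalidParameterError("distance_level must be in {1,2,3,4}")

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def read_zone_table(path: str | Path) -> ZoneTable:
    """Read a zone table TSV (columns: label, region_name, artery, distance_level)."""
    return ZoneTable(pd.read_csv(path, sep="\t"))


def starter_zone_table() -> ZoneTable:
    """Starter zoning with the level-1 assignments known from anatomy.

    Rostral anterior cingulate and medial orbitofrontal cortex sit at the
    ACA input, the parahippocampal gyrus at the PCA input, and the insula
    and transverse temporal gyrus at the MCA input.  Assignments beyond
    these must be supplied by the user for a full atlas.
    """
    rows = [
        (1, "rostralanteriorcingulate", "ACA", 1),
        (2, "medialorbitofrontal", "ACA", 1),
        (3, "parahippocampal", "PCA", 1),
        (4, "insula", "MCA", 1),
        (5, "transversetemporal", "MCA", 1),
    ]
    return ZoneTable(
        pd.DataFrame(rows, columns=["label", "region_name", "artery", "distance_level"])
    )


@dataclass(frozen=True)
class RoiWaveform:
    """Mean cardiac-gated waveform of one region or zone.

    ``modulation_amplitude`` is the peak-to-trough range (max − min) of the
    mean waveform, in percent.  ``se`` is the per-point SD/√n; NaN when the
    region holds a single voxel.
    """

    roi_id: object
    name: str
    mean: np.ndarray | None
    se: np.ndarray | None
    n_voxels: int
    modulation_amplitude: float

    @classmethod
    def from_stack(cls, roi_id, name, stack: np.ndarray) -> "RoiWaveform":
        n = stack.shape[0]
        if n == 0:
            return cls(roi_id, name, None, None, 0, float("nan"))
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(stack.shape[1], np.nan)
        amp = float(np.nanmax(mean) - np.nanmin(mean))
        return cls(roi_id, name, mean, se, n, amp)


def aggregate_roi(
    waveforms: np.ndarray,
    voxel_labels: np.ndarray,
    table: ZoneTable,
) -> list[RoiWaveform]:
    """Per-label mean waveform ± SE and modulation amplitude.

    ``waveforms`` is (n_voxels, n_grid); ``voxel_labels`` the label of each
    voxel (sampled from the label volume at the voxel indices).  Empty
    labels are reported with n_voxels = 0 and missing statistics.
    """
    W = np.asarray(waveforms, dtype=float)
    lab = np.asarray(voxel_labels)
    if W.shape[0] != lab.size:
        raise InvalidGeometryError("waveforms and voxel_labels differ in length")
    out = []
    for _, row in table.table.iterrows():
        members = W[lab == row["label"]]
        members = members[np.isfinite(members).all(axis=1)] if members.size else members
        out.append(RoiWaveform.from_stack(int(row["label"]), row["region_name"], members))
    return out


def aggregate_zones(
    waveforms: np.ndarray,
    voxel_labels: np.ndarray,
    table: ZoneTable,
) -> list[RoiWaveform]:
    """Per (artery × distance level) zone mean waveform and amplitude.

    Zone means average voxels (not member-region means), so the zone mean
    equals the count-weighted mean of its member regions.
    """
    W = np.asarray(waveforms, dtype=float)
    lab = np.asarray(voxel_labels)
    out = []
    for (artery, level), grp in table.table.groupby(["artery", "distance_level"]):
        sel = np.isin(lab, grp["label"].to_numpy())
        members = W[sel]
        members = members[np.isfinite(members).all(axis=1)] if members.size else members
        out.append(RoiWaveform.from_stack((artery, int(level)), f"{artery}-L{level}", members))
    return out


def amplitude_gradient_test(zones: list[RoiWaveform]) -> dict:
    """Per-artery monotonicity of modulation amplitude across distance levels.

    Pulsatility is expected to be largest at distance level 1 and fall off
    along the arterial tree.  Reports, per artery, the amplitude sequence
    and whether it is non-increasing (and strictly decreasing), with the
    first violating level if any.  Purely descriptive; no inferential
    statistic is attached.
    """
    by_artery: dict[str, dict[int, float]] = {}
    for z in zones:
        if not (isinstance(z.roi_id, tuple) and len(z.roi_id) == 2):
            raise InvalidParameterError("zones must come from aggregate_zones")
        artery, level = z.roi_id
        by_artery.setdefault(artery, {})[level] = z.modulation_amplitude
    report = {}
    for artery, amps in by_artery.items():
        levels = sorted(amps)
        seq = [amps[lv] for lv in levels]
        finite = [a for a in seq if np.isfinite(a)]
        violations = [
            levels[i + 1]
            for i in range(len(seq) - 1)
            if np.isfinite(seq[i]) and np.isfinite(seq[i + 1]) and seq[i + 1] > seq[i] + 1e-12
        ]
        report[artery] = {
            "levels": levels,
            "amplitudes": seq,
            "non_increasing": len(violations) == 0 and len(finite) >= 2,
            "strictly_decreasing": (
                len(finite) >= 2
                and all(
                    b < a - 1e-12
                    for a, b in zip(seq[:-1], seq[1:])
                    if np.isfinite(a) and np.isfinite(b)
                )
                and len(violations) == 0
            ),
            "violations_at_level": violations,
            "partial": len(finite) < len(seq),
        }
    return report


def zone_amplitudes_frame(zones: list[RoiWaveform]) -> pd.DataFrame:
    """Tabulate zone amplitudes for `zone_amplitudes.tsv`."""
    return pd.DataFrame(
        {
            "artery": [z.roi_id[0] for z in zones],
            "distance_level": [z.roi_id[1] for z in zones],
            "n_voxels": [z.n_voxels for z in zones],
            "modulation_amplitude": [z.modulation_amplitude for z in zones],
        }
    ).sort_values(["artery", "distance_level"], ignore_index=True)


def roi_waveforms_frame(rois: list[RoiWaveform], grid: np.ndarray) -> pd.DataFrame:
    """Long-format table of ROI mean waveforms for `roi_waveforms.tsv`."""
    frames = []
    for z in rois:
        if z.mean is None:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "roi": str(z.roi_id),
                    "name": z.name,
                    "cycle_fraction": grid,
                    "mean": z.mean,
                    "se": z.se,
                    "n_voxels": z.n_voxels,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["roi", "name", "cycle_fraction", "mean", "se", "n_voxels"]
        )
    return pd.concat(frames, ignore_index=True)
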