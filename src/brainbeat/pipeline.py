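"""End-to-end pipeline: physio → alignment → waveform model → ROI.

Runs every stage on one dataset, writes the standard-format outputs of each
module into an output directory, and produces a machine-readable
``report.json``.  Stage failures raise :class:`PipelineError` naming the
failing stage; outputs of completed stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import alignment, physio, roi, waveform_model
from .errors import BrainbeatError, PipelineError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CLI flags mirror these fields)."""

    fmri: str
    physio: str
    out: str
    fmri_json: str | None = None  # sidecar with RepetitionTime + SliceTiming
    labels: str | None = None
    zones: str | None = None
    truth: str | None = None  # simulator truth for recovery scoring
    n_drop: int = 3
    window: tuple[float, float] = (-0.5, 1.0)
    grid_size: int = 128
    r2_threshold: float = 50.0
    cv_threshold: float = 70.0
    k: int = 2
    search_window: tuple[float, float] = (-0.5, 0.66)
    resample_method: str = "mean-preserving"
    stop_after: str = "all"  # "align" | "model" | "all"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cv_threshold <= 100):
            raise PipelineError("config", "cv_threshold must be in (0, 100]")
        if self.k < 1:
            raise PipelineError("config", "k must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in cfg.items() if k in known})


def _load_timing(cfg: RunConfig, n_volumes: int) -> alignment.AcquisitionTiming:
    sidecar = cfg.fmri_json
    if sidecar is None:
        p = Path(cfg.fmri)
        name = p.name
        for suffix in (".nii.gz", ".nii"):
            if name.endswith(suffix):
                cand = p.with_name(name[: -len(suffix)] + ".json")
                if cand.exists():
                    sidecar = str(cand)
                break
    if sidecar is None:
        raise PipelineError("align", "no slice-timing sidecar found for the fMRI run")
    meta = json.loads(Path(sidecar).read_text())
    return alignment.timing_from_bids(meta["RepetitionTime"], meta["SliceTiming"], n_volumes)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the report dict (also written as report.json)."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in dataclasses.asdict(cfg).items()}}

    # --- physio stage -----------------------------------------------------
    try:
        if not Path(cfg.physio).exists():
            raise BrainbeatError(f"physio file not found: {cfg.physio}")
        trace = physio.read_bids_physio(cfg.physio)
        peaks = physio.detect_peaks(trace)
        hrv = physio.rmssd_hrv(
            peaks, trace_bounds=(trace.start_time, trace.start_time + trace.duration)
        )
        physio.write_peaks_tsv(peaks, out / "peaks.tsv")
        physio.write_hrv_json(hrv, out / "hrv.json")
        report["physio"] = {
            "n_beats": peaks.n_peaks,
            "mean_heart_rate_bpm": peaks.mean_heart_rate,
            "cycle_estimate_s": peaks.cycle_estimate,
            "max_rmssd_ms": hrv.max_rmssd,
            "rmssd_passes": hrv.passes_threshold,
        }
        logger.info("physio: %d beats, %.1f bpm", peaks.n_peaks, peaks.mean_heart_rate)
    except BrainbeatError as exc:
        raise PipelineError("physio", str(exc)) from exc

    # --- alignment stage --------------------------------------------------
    try:
        if not Path(cfg.fmri).exists():
            raise BrainbeatError(f"fMRI file not found: {cfg.fmri}")
        img = nib.load(cfg.fmri)
        timing = _load_timing(cfg, img.shape[3])
        aligned = alignment.align_volume(
            img, peaks, timing, n_drop=cfg.n_drop, window=cfg.window
        )
        aligned.save_r2(out / "r2.nii.gz")
        r2 = aligned.r2
        bands = {
            "r2>50": int(np.sum(r2 > 50)),
            "r2_30_50": int(np.sum((r2 > 30) & (r2 <= 50))),
            "r2_0_30": int(np.sum((r2 > 0) & (r2 <= 30))),
            "r2<=0": int(np.sum(r2 <= 0)),
        }
        report["alignment"] = {
            "n_voxels": aligned.n_voxels,
            "n_bins": aligned.n_bins,
            "voxel_counts_by_r2_band": bands,
        }
        logger.info("alignment: %d voxels, bands %s", aligned.n_voxels, bands)
    except BrainbeatError as exc:
        raise PipelineError("align", str(exc)) from exc

    if cfg.stop_after == "align":
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
        return report

    # --- waveform model stage ---------------------------------------------
    try:
        grid = waveform_model.cycle_fraction_grid(cfg.grid_size, cfg.window)
        n = aligned.n_voxels
        odd_w = np.full((n, grid.size), np.nan)
        even_w = np.full((n, grid.size), np.nan)
        for i in range(n):
            s = aligned.voxel_slice[i]
            o = waveform_model.resample_to_cycle(
                bin_centers_frac=aligned.bin_centers_frac[s],
                values=aligned.odd[i],
                grid=grid,
                method=cfg.resample_method,
            )
            e = waveform_model.resample_to_cycle(
                bin_centers_frac=aligned.bin_centers_frac[s],
                values=aligned.even[i],
                grid=grid,
                method=cfg.resample_method,
            )
            if o is not None:
                odd_w[i] = o
            if e is not None:
                even_w[i] = e
        train = waveform_model.build_matrix(odd_w, aligned.r2, grid, "odd")
        test_rows = even_w[train.voxel_ids]
        test = waveform_model.WaveformMatrix(
            matrix=np.nan_to_num(test_rows)
            / np.maximum(np.linalg.norm(np.nan_to_num(odd_w[train.voxel_ids]), axis=1), 1e-12)[:, None]
            * aligned.r2[train.voxel_ids, None],
            grid=grid,
            voxel_ids=train.voxel_ids,
            source_parity="even",
        )
        n_needed, cv_curve = waveform_model.components_required(
            train, test, threshold=cfg.cv_threshold
        )
        model = waveform_model.svd_decompose(train)
        pcs = waveform_model.CanonicalComponents(
            components=model.components[:, : cfg.k], grid=grid
        )
        fit_ok = np.isfinite(odd_w).all(axis=1) & np.isfinite(even_w).all(axis=1)
        fit = waveform_model.fit_betas(np.nan_to_num(odd_w), pcs)
        rr = waveform_model.rrmse(fit.predicted, np.nan_to_num(even_w), np.nan_to_num(odd_w))
        rr = np.where(fit_ok, rr, np.nan)

        shape3 = aligned.r2_map.shape
        idx = tuple(aligned.voxel_indices.T)
        affine = aligned.affine if aligned.affine is not None else np.eye(4)

        def save_map(values, name):
            vol = np.full(shape3, np.nan, dtype=np.float32)
            vol[idx] = values
            nib.save(nib.Nifti1Image(vol, affine), str(out / name))

        reliable = np.isfinite(aligned.r2) & (aligned.r2 > cfg.r2_threshold) & fit_ok
        t_min = np.full(n, np.nan)
        t_max = np.full(n, np.nan)
        for i in np.nonzero(reliable)[0]:
            t_min[i], t_max[i] = waveform_model.extrema_times(
                fit.predicted[i], grid, cfg.search_window
            )
        if not np.any(reliable):
            logger.warning(
                "no voxels exceed the R² display threshold %.1f; timing maps are empty",
                cfg.r2_threshold,
            )
        save_map(t_min, "t_min.nii.gz")
        save_map(t_max, "t_max.nii.gz")
        save_map(rr.astype(float), "rrmse.nii.gz")
        beta_vol = np.full(shape3 + (cfg.k,), np.nan, dtype=np.float32)
        beta_vol[idx] = fit.betas[:, : cfg.k]
        nib.save(nib.Nifti1Image(beta_vol, affine), str(out / "betas.nii.gz"))
        pc_df = pd.DataFrame({"cycle_fraction": grid})
        for kk in range(pcs.k):
            pc_df[f"pc{kk + 1}"] = pcs.components[:, kk]
        pc_df.to_csv(out / "canonical_pcs.tsv", sep="\t", index=False)
        (out / "model.json").write_text(
            json.dumps(
                {
                    "grid_size": cfg.grid_size,
                    "window": list(cfg.window),
                    "search_window": list(cfg.search_window),
                    "k": cfg.k,
                    "sign_convention": pcs.sign_convention,
                    "r2_threshold": cfg.r2_threshold,
                    "cv_threshold": cfg.cv_threshold,
                    "cv_variance_explained": cv_curve[: max(cfg.k, n_needed)],
                    "n_components_over_threshold": n_needed,
                },
                indent=2,
            )
        )
        with np.errstate(invalid="ignore"):
            frac_rrmse_lt1 = float(np.mean(rr[np.isfinite(rr)] < 1)) if np.any(np.isfinite(rr)) else float("nan")
        report["model"] = {
            "n_modeled_voxels": int(train.n_voxels),
            "cv_variance_explained_k": cv_curve[: max(cfg.k, n_needed)],
            "n_components_over_threshold": n_needed,
            "fraction_rrmse_lt_1": frac_rrmse_lt1,
            "n_timed_voxels": int(np.sum(reliable)),
        }
    except BrainbeatError as exc:
        raise PipelineError("model", str(exc)) from exc

    # --- ROI stage (optional) ---------------------------------------------
    if cfg.labels is not None and cfg.stop_after == "all":
        try:
            lab_img = nib.load(cfg.labels)
            lab = np.asarray(lab_img.get_fdata()).astype(int)
            vox_lab = lab[idx]
            table = (
                roi.read_zone_table(cfg.zones) if cfg.zones else roi.starter_zone_table()
            )
            wav = np.nan_to_num(odd_w)
            rois = roi.aggregate_roi(wav, vox_lab, table)
            zones = roi.aggregate_zones(wav, vox_lab, table)
            roi.roi_waveforms_frame(rois, grid).to_csv(
                out / "roi_waveforms.tsv", sep="\t", index=False, na_rep="n/a"
            )
            roi.zone_amplitudes_frame(zones).to_csv(
                out / "zone_amplitudes.tsv", sep="\t", index=False, na_rep="n/a"
            )
            report["roi"] = {
                "zone_amplitudes": {
                    f"{z.roi_id[0]}-L{z.roi_id[1]}": z.modulation_amplitude for z in zones
                },
                "gradient": roi.amplitude_gradient_test(zones),
            }
        except BrainbeatError as exc:
            raise PipelineError("roi", str(exc)) from exc

    # --- recovery scoring against simulator truth (optional) ---------------
    if cfg.truth is not None:
        report["recovery"] = _score_recovery(
            cfg, aligned, fit.predicted, grid, t_min, t_max, reliable
        )

    report_path = out / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2))
    logger.info("report written to %s", report_path)
    return report


def _score_recovery(cfg, aligned, predicted, grid, t_min, t_max, reliable) -> dict:
    """Compare recovered extrema against the simulator's generating truth."""
    truth = json.loads(Path(cfg.truth).read_text())
    codes = {int(v): k for k, v in truth["class_codes"].items()}
    lab_path = Path(cfg.truth).parent / "labels.nii.gz"
    class_map = np.asarray(nib.load(str(lab_path)).get_fdata()).astype(int)
    vox_class = class_map[tuple(aligned.voxel_indices.T)]
    out: dict = {}
    for code, name in codes.items():
        if name == "null":
            continue
        tpl = truth["templates"][name]
        sel = (vox_class == code) & reliable
        n_sel = int(np.sum(sel))
        if n_sel == 0:
            out[name] = {"n_reliable": 0}
            continue
        rec = t_min[sel] if tpl["sign"] < 0 else t_max[sel]
        err = rec - tpl["extremum_frac"]
        # correct sign: the largest-|value| modeled extremum matches the class sign
        sign_ok = []
        for i in np.nonzero(sel)[0]:
            y = predicted[i]
            m = (grid >= cfg.search_window[0]) & (grid <= cfg.search_window[1])
            ys = y[m]
            dominant = np.sign(ys[np.argmax(np.abs(ys))])
            sign_ok.append(dominant == np.sign(tpl["sign"]))
        out[name] = {
            "n_reliable": n_sel,
            "frac_within_0.05": float(np.mean(np.abs(err) <= 0.05)),
            "median_abs_error_frac": float(np.median(np.abs(err))),
            "frac_correct_sign": float(np.mean(sign_ok)),
        }
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
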