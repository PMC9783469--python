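"""SVD modeling of cardiac-gated waveforms and extrema-timing extraction.

The cardiac-gated waveforms of all reliable voxels, each scaled so that its
amplitude equals its test–retest R², form a matrix M (voxels × time) that is
decomposed as M = UΣV*.  Performing the decomposition on the odd-beat half
and projecting the even-beat half onto the leading components gives a
cross-validated variance-explained curve; two components typically suffice.
Stacking each subject's leading components and running a second SVD (leaving
one subject out) yields canonical components pc₁…pcₙ; any voxel's waveform
is then modeled as Y = β₁pc₁ + … + βₙpcₙ + ε.  Model fit is scored by

    Rrmse = Mrmse / Drmse

the ratio of the model's RMS prediction error on the even half to the RMS
even-odd difference; a perfect model of a signal with additive zero-mean
Gaussian noise has expectation 1/√2, and Rrmse < 1 means the model beats
within-run test–retest.  The modeled waveform's local minimum and maximum
(in cycle fractions) map the timing of blood and CSF pulses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import AlignedResponse
from .errors import ConfigurationError, InvalidParameterError, ModelError

__all__ = [
    "cycle_fraction_grid",
    "WaveformMatrix",
    "SvdModel",
    "CanonicalComponents",
    "ModelFit",
    "resample_to_cycle",
    "build_matrix",
    "svd_decompose",
    "cv_variance_explained",
    "components_required",
    "canonical_components",
    "fit_betas",
    "rrmse",
    "extrema_times",
]

DEFAULT_GRID_SIZE = 128
DEFAULT_SEARCH_WINDOW = (-0.5, 0.66)


def cycle_fraction_grid(
    n: int = DEFAULT_GRID_SIZE, window: tuple[float, float] = (-0.5, 1.0)
) -> np.ndarray:
    """Standardized cycle-fraction grid: ``n`` evenly spaced points on
    [window[0], window[1])."""
    lo, hi = window
    return lo + (hi - lo) * np.arange(n) / n


def resample_to_cycle(
    resp: AlignedResponse | None = None,
    grid: np.ndarray | None = None,
    parity: str = "odd",
    method: str = "linear",
    *,
    bin_centers_frac: np.ndarray | None = None,
    values: np.ndarray | None = None,
) -> np.ndarray | None:
    """Interpolate a binned waveform onto the cycle-fraction grid.

    Accepts either an :class:`AlignedResponse` (``parity`` selects the odd
    or even half) or raw ``bin_centers_frac``/``values`` arrays.  Grid
    points outside the sampled range take the edge value.  Returns None
    when fewer than 2 bins are defined (voxel excluded).

    ``method`` is ``"linear"``, ``"cubic"`` (natural cubic spline) or
    ``"mean-preserving"`` (histospline).  Linear interpolation pins every
    local extremum of the resampled curve to a bin center, which quantizes
    extremum timing to the bin width and biases the extrema of asymmetric
    (fast-onset/slow-return) transients toward the shallow side by up to
    half a bin.  The mean-preserving histospline additionally treats bin
    values as the window averages they are; it restores sub-bin extremum
    resolution and is the pipeline's timing-path default.
    """
    if grid is None:
        grid = cycle_fraction_grid()
    if resp is not None:
        bin_centers_frac = resp.bin_centers_frac
        values = resp.even_mean if parity == "even" else resp.odd_mean
    x = np.asarray(bin_centers_frac, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return None
    x, y = x[ok], y[ok]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if method == "linear" or ok.sum() < 4:
        return np.interp(grid, x, y)
    from scipy.interpolate import CubicSpline

    if method == "cubic":
        spline = CubicSpline(x, y, bc_type="natural")
        return spline(np.clip(grid, x[0], x[-1]))
    if method == "mean-preserving":
        # histospline: bin values are window averages, so interpolate the
        # cumulative integral and differentiate — undoes the first-order
        # extremum smear of bin averaging
        edges = np.empty(x.size + 1)
        edges[1:-1] = 0.5 * (x[:-1] + x[1:])
        edges[0] = x[0] - (edges[1] - x[0])
        edges[-1] = x[-1] + (x[-1] - edges[-2])
        F = np.concatenate([[0.0], np.cumsum(y * np.diff(edges))])
        spline = CubicSpline(edges, F, bc_type="natural")
        return spline.derivative()(np.clip(grid, edges[0], edges[-1]))
    raise InvalidParameterError(f"unknown resampling method {method!r}")


@dataclass(frozen=True)
class WaveformMatrix:
    """Voxels × time matrix whose row norms equal each voxel's R².

    Rows are unit-normalized resampled waveforms multiplied by max(R², 0);
    voxels with non-positive or undefined R² are pruned (``voxel_ids`` maps
    rows back to the caller's voxel indexing).
    """

    matrix: np.ndarray
    grid: np.ndarray
    voxel_ids: np.ndarray
    source_parity: str = "odd"

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]


def build_matrix(
    waveforms: np.ndarray,
    r2: np.ndarray,
    grid: np.ndarray,
    source_parity: str = "odd",
) -> WaveformMatrix:
    """Assemble the R²-scaled waveform matrix M.

    ``waveforms`` is (n_voxels, n_grid) of resampled waveforms (NaN rows
    allowed); each retained row is scaled to unit norm then multiplied by
    its R², so the most reliable voxels dominate the decomposition.
    """
    W = np.asarray(waveforms, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if W.ndim != 2 or W.shape[0] != r2.size:
        raise InvalidParameterError("waveforms must be (n_voxels, n_grid) matching r2")
    norms = np.linalg.norm(np.nan_to_num(W), axis=1)
    keep = np.isfinite(r2) & (r2 > 0) & (norms > 0) & np.isfinite(W).all(axis=1)
    if not np.any(keep):
        raise ModelError("no voxels with positive reliability to model")
    ids = np.nonzero(keep)[0]
    M = W[keep] / norms[keep, None] * r2[keep, None]
    return WaveformMatrix(matrix=M, grid=np.asarray(grid), voxel_ids=ids,
                          source_parity=source_parity)


def _fix_signs(components: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: each component is negative at cycle
    fraction 0 (blood dips at the PPG peak); if its value there is ~0 the
    sign of its largest-magnitude element decides."""
    comps = components.copy()
    idx0 = int(np.argmin(np.abs(grid)))
    for k in range(comps.shape[1]):
        v = comps[idx0, k]
        if abs(v) < 1e-12 * max(1.0, np.abs(comps[:, k]).max()):
            v = comps[np.argmax(np.abs(comps[:, k])), k]
        if v > 0:
            comps[:, k] *= -1.0
    return comps


@dataclass(frozen=True)
class SvdModel:
    """Thin SVD of a waveform matrix: M = spatial_weights · diag(σ) · componentsᵀ.

    ``components`` columns are unit-norm time courses on the grid (sign
    fixed), ``spatial_weights`` the per-voxel loadings.
    """

    components: np.ndarray  # (n_grid, k)
    singular_values: np.ndarray  # (k,) descending
    spatial_weights: np.ndarray  # (n_voxels, k)
    grid: np.ndarray

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        k = self.singular_values.size if k is None else k
        return (
            self.spatial_weights[:, :k]
            * self.singular_values[:k]
        ) @ self.components[:, :k].T


def svd_decompose(M: WaveformMatrix) -> SvdModel:
    """Thin SVD of the R²-weighted waveform matrix."""
    A = M.matrix
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ModelError("matrix must be at least 2 x 2")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[0] <= 0:
        raise ModelError("rank-0 matrix")
    comps = Vt.T
    fixed = _fix_signs(comps, M.grid)
    flips = np.sign(np.sum(fixed * comps, axis=0))
    return SvdModel(
        components=fixed,
        singular_values=s,
        spatial_weights=U * flips,
        grid=M.grid,
    )


def cv_variance_explained(train: WaveformMatrix, test: WaveformMatrix, k: int) -> float:
    """Percent of test-half variance captured by the first ``k`` training
    components.

    The training (odd-beat) matrix is decomposed; test (even-beat) rows are
    projected onto the span of the first k time components and the
    cross-validated variance explained is 100·(1 − Σ‖test − proj‖²/Σ‖test‖²).
    """
    if train.matrix.shape[1] != test.matrix.shape[1]:
        raise InvalidParameterError("train/test grids differ")
    if k < 0:
        raise InvalidParameterError("k must be >= 0")
    if k == 0:
        return 0.0
    model = svd_decompose(train)
    rank = model.singular_values.size
    k = min(k, rank)
    C = model.components[:, :k]  # (T, k), orthonormal
    T = test.matrix
    proj = (T @ C) @ C.T
    total = float(np.sum(T**2))
    if total == 0:
        raise ModelError("test matrix is all zero")
    resid = float(np.sum((T - proj) ** 2))
    return 100.0 * (1.0 - resid / total)


def components_required(
    train: WaveformMatrix, test: WaveformMatrix, threshold: float = 70.0
) -> tuple[int, list[float]]:
    """Smallest number of components whose cross-validated variance
    explained exceeds ``threshold`` percent, plus the full curve."""
    model = svd_decompose(train)
    rank = model.singular_values.size
    curve = [cv_variance_explained(train, test, k) for k in range(1, rank + 1)]
    for k, v in enumerate(curve, start=1):
        if v > threshold:
            return k, curve
    return rank, curve


@dataclass(frozen=True)
class CanonicalComponents:
    """Canonical time courses shared across subjects (leave-one-out)."""

    components: np.ndarray  # (n_grid, k) orthonormal, sign-fixed
    grid: np.ndarray
    training_subjects: tuple = ()
    sign_convention: str = "component negative at cycle fraction 0"

    @property
    def k(self) -> int:
        return self.components.shape[1]


def canonical_components(
    subject_components: dict[object, np.ndarray],
    held_out: object | None = None,
    k: int = 2,
) -> CanonicalComponents:
    """Second-level SVD across subjects' leading components.

    ``subject_components`` maps subject id → (n_grid, k_subj) component
    array on the common grid.  The held-out subject is excluded from
    training; each training component is unit-normalized, all are stacked
    as rows, and the first ``k`` right singular vectors (time courses) of
    the stack become the canonical components.
    """
    if held_out is not None and held_out not in subject_components:
        raise ConfigurationError(f"held_out subject {held_out!r} not found")
    training = {s: c for s, c in subject_components.items() if s != held_out}
    if len(training) == 0:
        raise ConfigurationError("no training subjects")
    if len(training) == 1:
        warnings.warn(
            "single training subject: canonical components degenerate to that "
            "subject's components",
            stacklevel=2,
        )
    rows, grids = [], []
    for sid, comps in training.items():
        comps = np.asarray(comps, dtype=float)
        if comps.ndim != 2:
            raise InvalidParameterError(f"components of {sid!r} must be 2-D")
        for col in comps.T:
            n = np.linalg.norm(col)
            if n > 0:
                rows.append(col / n)
        grids.append(comps.shape[0])
    if len(set(grids)) != 1:
        raise ConfigurationError("subject components are not on a common grid")
    S = np.vstack(rows)
    _, s, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(k, int(np.sum(s > 1e-12)))
    comps = _fix_signs(Vt[:k].T, cycle_fraction_grid(S.shape[1]))
    return CanonicalComponents(
        components=comps,
        grid=cycle_fraction_grid(S.shape[1]),
        training_subjects=tuple(training.keys()),
    )


@dataclass(frozen=True)
class ModelFit:
    """Least-squares fit of canonical components to one voxel's waveform."""

    betas: np.ndarray
    predicted: np.ndarray
    residual: np.ndarray


def fit_betas(Y: np.ndarray, pcs: CanonicalComponents | np.ndarray) -> ModelFit:
    """β weights of Y = β₁pc₁ + … + βₙpcₙ + ε.

    With orthonormal components the least-squares solution is the vector of
    inner products.  Works on a single waveform (n_grid,) or a stack
    (n_voxels, n_grid).
    """
    C = pcs.components if isinstance(pcs, CanonicalComponents) else np.asarray(pcs)
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise InvalidParameterError("Y contains non-finite values")
    gram = C.T @ C
    if not np.allclose(gram, np.eye(C.shape[1]), atol=1e-8):
        raise InvalidParameterError("components must be orthonormal")
    betas = Y @ C  # (…, k)
    predicted = betas @ C.T
    return ModelFit(betas=betas, predicted=predicted, residual=Y - predicted)


def rrmse(predicted: np.ndarray, even: np.ndarray, odd: np.ndarray) -> np.ndarray:
    """Relative RMS error: Mrmse/Drmse.

    Mrmse is the RMS difference between the model prediction (fitted on the
    odd half) and the even half; Drmse the RMS even-odd difference.  Values
    < 1 mean the model predicts the held-out half better than test–retest.
    Drmse = 0 with Mrmse > 0 → inf; both zero → 0.  Vectorized over leading
    axes.
    """
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(even, dtype=float)
    o = np.asarray(odd, dtype=float)
    m = np.sqrt(np.mean((e - p) ** 2, axis=-1))
    d = np.sqrt(np.mean((e - o) ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(d > 0, m / np.where(d > 0, d, 1.0), np.where(m > 0, np.inf, 0.0))
    return out if out.ndim else float(out)


def extrema_times(
    waveform: np.ndarray,
    grid: np.ndarray,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
) -> tuple[float, float]:
    """Cycle fractions of the modeled waveform's minimum and maximum.

    The global extrema inside ``search_window`` are located on the grid and
    refined by 3-point parabolic interpolation (skipped at window edges).
    Ties break toward the earliest time.  A flat waveform returns
    (nan, nan) — the voxel should be masked.
    """
    y = np.asarray(waveform, dtype=float)
    g = np.asarray(grid, dtype=float)
    sel = np.nonzero((g >= search_window[0]) & (g <= search_window[1]))[0]
    if sel.size < 3:
        raise InvalidParameterError("search window contains fewer than 3 grid points")
    ys = y[sel]
    if not np.all(np.isfinite(ys)) or np.ptp(ys) == 0:
        return (float("nan"), float("nan"))
    step = g[1] - g[0]

    def refine(i_local: int, yy: np.ndarray) -> float:
        i = sel[i_local]
        if i_local == 0 or i_local == sel.size - 1:
            return float(g[i])
        y0, y1, y2 = yy[i_local - 1], yy[i_local], yy[i_local + 2 - 1]
        denom = y0 - 2 * y1 + y2
        if denom == 0:
            return float(g[i])
        delta = 0.5 * (y0 - y2) / denom
        return float(g[i] + np.clip(delta, -0.5, 0.5) * step)

    t_min = refine(int(np.argmin(ys)), ys)
    t_max = refine(int(np.argmax(ys)), ys)
    return (t_min, t_max)
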