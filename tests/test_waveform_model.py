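"""SVD waveform model: resampling, components, betas, Rrmse, extrema."""

import numpy as np
import pytest

import brainbeat as bb
from brainbeat.errors import ConfigurationError, InvalidParameterError, ModelError


GRID = bb.cycle_fraction_grid()


def _principal_angles_deg(A, B):
    """Angles between the column spaces of A and B (orthonormalized)."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s, -1, 1)))


class TestResample:
    def test_identity_on_grid(self):
        y = np.sin(2 * np.pi * GRID)
        out = bb.resample_to_cycle(bin_centers_frac=GRID, values=y, grid=GRID)
        assert np.allclose(out, y)

    def test_linear_ramp_exact(self):
        centers = np.linspace(-0.5, 0.95, 30)
        y = 2.0 * centers + 1.0
        out = bb.resample_to_cycle(bin_centers_frac=centers, values=y, grid=GRID)
        interior = (GRID >= centers[0]) & (GRID <= centers[-1])
        assert np.allclose(out[interior], 2.0 * GRID[interior] + 1.0, atol=1e-12)

    def test_cosine_twenty_bins_within_tolerance(self):
        centers = -0.5 + (np.arange(30) + 0.5) * 0.05
        y = np.cos(2 * np.pi * centers)
        out = bb.resample_to_cycle(bin_centers_frac=centers, values=y, grid=GRID)
        interior = (GRID >= centers[0]) & (GRID <= centers[-1])
        assert np.abs(out[interior] - np.cos(2 * np.pi * GRID[interior])).max() < 0.015

    def test_all_missing_excluded(self):
        out = bb.resample_to_cycle(
            bin_centers_frac=np.full(5, np.nan), values=np.full(5, np.nan), grid=GRID
        )
        assert out is None

    def test_mean_preserving_recovers_asymmetric_extremum(self):
        """Bin averages of a skewed transient: histospline reconstruction
        locates the extremum better than plain cubic through the centers."""
        edges = -0.5 + np.arange(31) * 0.05
        centers = 0.5 * (edges[:-1] + edges[1:])
        fine = np.linspace(-0.025, 0.025, 201)
        w = bb.waveform_template("artery")
        yavg = np.array([w(c + fine).mean() for c in centers])
        rec = bb.resample_to_cycle(
            bin_centers_frac=centers, values=yavg, grid=GRID, method="mean-preserving"
        )
        t_min, _ = bb.extrema_times(rec, GRID)
        assert t_min == pytest.approx(-0.15, abs=0.012)


class TestBuildMatrix:
    def test_row_norms_equal_r2(self):
        w = np.tile(np.sin(2 * np.pi * GRID), (2, 1))
        M = bb.build_matrix(w, np.array([100.0, 50.0]), GRID)
        assert np.allclose(np.linalg.norm(M.matrix, axis=1), [100.0, 50.0])

    def test_negative_r2_pruned(self):
        w = np.tile(np.sin(2 * np.pi * GRID), (3, 1))
        M = bb.build_matrix(w, np.array([80.0, -5.0, np.nan]), GRID)
        assert M.n_voxels == 1
        assert list(M.voxel_ids) == [0]

    def test_empty_matrix_raises(self):
        with pytest.raises(ModelError):
            bb.build_matrix(np.zeros((2, GRID.size)), np.array([-1.0, -2.0]), GRID)

    def test_rows_cluster_by_template(self, rng):
        names = ["artery", "csf"]
        rows, r2 = [], []
        for name in names:
            w = bb.waveform_template(name)(GRID)
            for _ in range(20):
                rows.append(w + rng.normal(0, 0.02, GRID.size))
                r2.append(70.0)
        M = bb.build_matrix(np.array(rows), np.array(r2), GRID)
        for j, name in enumerate(names):
            tpl = bb.waveform_template(name)(GRID)
            tpl = tpl / np.linalg.norm(tpl)
            block = M.matrix[20 * j : 20 * (j + 1)]
            cos = block @ tpl / np.linalg.norm(block, axis=1)
            assert np.all(np.abs(cos) > 0.9)


class TestSvd:
    def test_rank_one_recovers_generating_course(self):
        course = np.sin(2 * np.pi * GRID)
        course /= np.linalg.norm(course)
        M = bb.WaveformMatrix((np.arange(1, 6)[:, None] * course), GRID, np.arange(5))
        model = bb.svd_decompose(M)
        assert model.singular_values[0] > 0
        assert model.singular_values[1] == pytest.approx(0.0, abs=1e-10)
        assert abs(np.dot(model.components[:, 0], course)) == pytest.approx(1.0, abs=1e-9)

    def test_components_orthonormal_and_reconstruction(self, rng):
        M = bb.WaveformMatrix(rng.normal(size=(40, GRID.size)), GRID, np.arange(40))
        model = bb.svd_decompose(M)
        k = model.singular_values.size
        assert np.allclose(model.components.T @ model.components, np.eye(k), atol=1e-10)
        assert np.allclose(model.reconstruct(), M.matrix, atol=1e-8)

    def test_sign_convention_negative_at_peak(self, resampled_waveforms, sms_dataset):
        aligned = sms_dataset["aligned"]
        M = bb.build_matrix(
            resampled_waveforms["odd"], aligned.r2, resampled_waveforms["grid"]
        )
        model = bb.svd_decompose(M)
        idx0 = int(np.argmin(np.abs(GRID)))
        assert model.components[idx0, 0] < 0

    def test_rank_two_plus_noise_spans_generators(self, rng):
        c1 = bb.waveform_template("artery")(GRID)
        c2 = bb.waveform_template("csf")(GRID)
        B = rng.normal(size=(300, 2))
        data = B @ np.vstack([c1, c2]) + rng.normal(0, 0.05, (300, GRID.size))
        M = bb.build_matrix(data, np.full(300, 70.0), GRID)
        model = bb.svd_decompose(M)
        ang = _principal_angles_deg(model.components[:, :2], np.column_stack([c1, c2]))
        assert ang.max() < 10.0


class TestCrossValidation:
    def test_self_projection_monotone_to_100(self, rng):
        M = bb.WaveformMatrix(rng.normal(size=(30, 16)), np.arange(16), np.arange(30))
        curve = [bb.cv_variance_explained(M, M, k) for k in range(0, 17)]
        assert curve[0] == 0.0
        assert np.all(np.diff(curve) >= -1e-9)
        assert curve[-1] == pytest.approx(100.0, abs=1e-8)

    def test_held_out_monotone(self, rng):
        c = np.vstack([bb.waveform_template("artery")(GRID), bb.waveform_template("csf")(GRID)])
        B = rng.normal(size=(200, 2))
        train = bb.build_matrix(B @ c + rng.normal(0, 0.1, (200, GRID.size)), np.full(200, 70.0), GRID)
        test = bb.build_matrix(B @ c + rng.normal(0, 0.1, (200, GRID.size)), np.full(200, 70.0), GRID)
        curve = [bb.cv_variance_explained(train, test, k) for k in range(1, 6)]
        assert np.all(np.diff(curve) >= -1e-9)
        k_needed, _ = bb.components_required(train, test, threshold=70.0)
        assert k_needed == 2


class TestCanonicalComponents:
    def _subject(self, angle_deg):
        c1 = bb.waveform_template("artery")(GRID)
        c2 = bb.waveform_template("csf")(GRID)
        Q, _ = np.linalg.qr(np.column_stack([c1, c2]))
        a = np.radians(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return Q @ R

    def test_identical_subjects_reproduced(self):
        comps = self._subject(0.0)
        out = bb.canonical_components({"a": comps, "b": comps, "c": comps}, held_out=None)
        ang = _principal_angles_deg(out.components, comps)
        assert ang.max() < 1e-6

    def test_rotated_subjects_recover_common_pair(self):
        subjects = {f"s{i}": self._subject(a) for i, a in enumerate([-4, -2, 0, 2, 4])}
        out = bb.canonical_components(subjects, held_out="s2")
        assert "s2" not in out.training_subjects
        ang = _principal_angles_deg(out.components, self._subject(0.0))
        assert ang.max() < 5.0

    def test_single_training_subject_warns(self):
        comps = self._subject(0.0)
        with pytest.warns(UserWarning):
            out = bb.canonical_components({"a": comps, "b": comps}, held_out="b")
        ang = _principal_angles_deg(out.components, comps)
        assert ang.max() < 1e-6

    def test_unknown_held_out_rejected(self):
        with pytest.raises(ConfigurationError):
            bb.canonical_components({"a": self._subject(0)}, held_out="zz")


class TestFitBetas:
    def _pcs(self):
        return bb.CanonicalComponents(components=self._ortho(), grid=GRID)

    @staticmethod
    def _ortho():
        c1 = bb.waveform_template("artery")(GRID)
        c2 = bb.waveform_template("csf")(GRID)
        Q, _ = np.linalg.qr(np.column_stack([c1, c2]))
        return Q

    def test_pc1_recovered_exactly(self):
        pcs = self._pcs()
        fit = bb.fit_betas(pcs.components[:, 0], pcs)
        assert np.allclose(fit.betas, [1.0, 0.0], atol=1e-12)

    def test_exact_span_membership(self):
        pcs = self._pcs()
        Y = 3.0 * pcs.components[:, 0] - 2.0 * pcs.components[:, 1]
        fit = bb.fit_betas(Y, pcs)
        assert np.allclose(fit.betas, [3.0, -2.0], atol=1e-10)
        assert np.allclose(fit.residual, 0.0, atol=1e-10)

    def test_monte_carlo_unbiased_with_expected_se(self, rng):
        """With orthonormal regressors the LS betas are unbiased with
        SE = sigma per component (closed-form check)."""
        pcs = self._pcs()
        sigma = 0.3
        true = np.array([2.0, -1.0])
        Y = true @ pcs.components.T + rng.normal(0, sigma, (500, GRID.size))
        fit = bb.fit_betas(Y, pcs)
        assert np.allclose(fit.betas.mean(axis=0), true, atol=4 * sigma / np.sqrt(500))
        assert np.allclose(fit.betas.std(axis=0), sigma, rtol=0.2)

    def test_non_orthonormal_rejected(self):
        C = np.column_stack([GRID, GRID * 2])
        with pytest.raises(InvalidParameterError):
            bb.fit_betas(np.zeros(GRID.size), C)


class TestRrmse:
    def test_perfect_prediction_zero(self):
        e = np.sin(GRID)
        assert bb.rrmse(e, e, np.cos(GRID)) == 0.0

    def test_predicted_equals_odd_gives_one(self, rng):
        e, o = rng.normal(size=16), rng.normal(size=16)
        assert bb.rrmse(o, e, o) == pytest.approx(1.0)

    def test_degenerate_cases(self):
        z = np.zeros(8)
        assert bb.rrmse(z, z, z) == 0.0
        assert np.isinf(bb.rrmse(np.ones(8), z, z))


class TestExtrema:
    def test_negative_cosine(self):
        y = -np.cos(2 * np.pi * GRID)
        t_min, t_max = bb.extrema_times(y, GRID)
        assert t_min == pytest.approx(0.0, abs=1e-6)
        assert t_max == pytest.approx(-0.5, abs=0.02)  # window edge, no refinement

    @pytest.mark.parametrize("name,which,true_t", [("artery", 0, -0.15), ("csf", 1, 0.05)])
    def test_template_extrema_within_one_grid_step(self, name, which, true_t):
        y = bb.waveform_template(name)(GRID)
        times = bb.extrema_times(y, GRID)
        step = GRID[1] - GRID[0]
        assert times[which] == pytest.approx(true_t, abs=step)

    def test_flat_waveform_masked(self):
        t_min, t_max = bb.extrema_times(np.zeros(GRID.size), GRID)
        assert np.isnan(t_min) and np.isnan(t_max)

    def test_tie_break_earliest(self):
        y = np.zeros(GRID.size)
        y[10] = y[20] = -1.0
        t_min, _ = bb.extrema_times(y, GRID)
        assert t_min <= GRID[10] + 1e-9


class TestScaleEquivariance:
    def test_global_scaling_leaves_model_outputs_unchanged(self, rng):
        c1 = bb.waveform_template("artery")(GRID)
        c2 = bb.waveform_template("csf")(GRID)
        data = rng.normal(size=(100, 2)) @ np.vstack([c1, c2])
        data += rng.normal(0, 0.05, data.shape)
        r2 = np.full(100, 60.0)
        scale = 7.3

        def run(w, r):
            M = bb.build_matrix(w, r, GRID)
            model = bb.svd_decompose(M)
            pcs = bb.CanonicalComponents(components=model.components[:, :2], grid=GRID)
            fit = bb.fit_betas(w, pcs)
            t = np.array([bb.extrema_times(fit.predicted[i], GRID) for i in range(5)])
            return model.components[:, :2], fit.betas, t

        comps_a, betas_a, t_a = run(data, r2)
        comps_b, betas_b, t_b = run(scale * data, scale * r2)
        assert np.allclose(np.abs(comps_a), np.abs(comps_b), atol=1e-8)
        ratio_a = betas_a[:, 0] / betas_a[:, 1]
        ratio_b = betas_b[:, 0] / betas_b[:, 1]
        assert np.allclose(ratio_a, ratio_b, rtol=1e-6)
        assert np.allclose(t_a, t_b, atol=1e-9, equal_nan=True)
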