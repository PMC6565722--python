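"""Resampling, template selection, SVD shape bases and feature assembly."""
import numpy as np
import pytest

from ppgbp import features as ft
from ppgbp.exceptions import (
    FeatureAssemblyError,
    InsufficientCyclesError,
    RankDeficiencyError,
)
from ppgbp.signal import SDPTG, FLAG_SDPTG_INCOMPLETE


class TestResample:
    def test_identity_on_32_points(self):
        x = np.random.default_rng(0).normal(size=32)
        assert np.allclose(ft.resample_beat(x, 32), x)

    def test_linear_ramp_preserves_endpoints_and_linearity(self):
        out = ft.resample_beat(np.arange(64.0), 32)
        assert out[0] == 0.0 and out[-1] == 63.0
        assert np.allclose(np.diff(out), np.diff(out)[0])

    def test_analytic_waveform_within_interpolation_bound(self):
        # sampled sine resampled to 32 points vs the analytic values there:
        # linear-interpolation error bound h^2/8 * max|f''|
        n, fs = 55, 50.0
        t = np.arange(n) / fs
        f = lambda u: np.sin(2 * np.pi * 1.3 * u)
        out = ft.resample_beat(f(t), 32)
        grid = np.linspace(0, (n - 1) / fs, 32)
        h = 1.0 / fs
        bound = h**2 / 8 * (2 * np.pi * 1.3) ** 2
        assert np.max(np.abs(out - f(grid))) <= bound + 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ft.resample_beat(np.array([1.0, 2.0, 3.0]), 32)


class TestTemplate:
    def test_identical_beats_return_that_beat(self):
        x = np.random.default_rng(1).normal(size=32)
        assert np.allclose(ft.build_template(np.tile(x, (7, 1))), x)

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        shapes = rng.normal(size=(9, 32))
        t0 = ft.build_template(shapes)
        t1 = ft.build_template(shapes[rng.permutation(9)])
        assert np.allclose(t0, t1)

    def test_median_rejects_single_corrupted_beat(self):
        clean = np.linspace(0, 1, 32)
        shapes = np.tile(clean, (10, 1))
        shapes[7] += 5.0
        assert np.allclose(ft.build_template(shapes), clean)


class TestSelectBeats:
    def test_exactly_k_returns_all(self):
        shapes = np.random.default_rng(3).normal(size=(30, 32))
        idx = ft.select_beats(shapes, shapes.mean(0), 30)
        assert np.array_equal(np.sort(idx), np.arange(30))

    def test_distorted_beats_excluded(self):
        rng = np.random.default_rng(4)
        clean = np.sin(np.linspace(0, 2 * np.pi, 32))
        shapes = clean + 0.01 * rng.normal(size=(40, 32))
        bad = rng.choice(40, 10, replace=False)
        shapes[bad] += 3.0
        sel = ft.select_beats(shapes, clean, 30)
        assert set(sel).isdisjoint(set(bad))

    def test_selected_distances_globally_minimal(self):
        rng = np.random.default_rng(5)
        shapes = rng.normal(size=(45, 32))
        tmpl = shapes.mean(0)
        sel = ft.select_beats(shapes, tmpl, 30)
        d = np.linalg.norm(shapes - tmpl, axis=1)
        assert d[sel].max() <= d[np.setdiff1d(np.arange(45), sel)].min() + 1e-12

    def test_tie_broken_by_earlier_index(self):
        shapes = np.zeros((4, 32))
        shapes[1] += 1.0  # distance 32^0.5
        shapes[3] += 1.0  # identical distance, later index
        sel = ft.select_beats(shapes, np.zeros(32), 3)
        assert 1 in sel and 3 not in sel

    def test_insufficient_cycles(self):
        with pytest.raises(InsufficientCyclesError):
            ft.select_beats(np.zeros((10, 32)), np.zeros(32), 30)


class TestWaveformBasis:
    def test_rank_one_data_explains_everything(self):
        rng = np.random.default_rng(6)
        direction = rng.normal(size=32)
        coeffs = rng.normal(size=20)
        X = np.outer(coeffs, direction)
        basis = ft.fit_waveform_basis(X, 1)
        assert basis.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_projection_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 32)) @ rng.normal(size=(32, 32))
        basis = ft.fit_waveform_basis(X, 4)
        # oracle: eigenvectors of the covariance matrix
        Xc = X - X.mean(0)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        v = v[:, order[:4]].T
        for j in range(4):  # align signs
            if v[j, np.argmax(np.abs(v[j]))] < 0:
                v[j] = -v[j]
        assert np.allclose(np.abs(basis.components), np.abs(v), rtol=0, atol=1e-6)
        p_impl = ft.project_beat(X[0], basis)
        p_oracle = (X[0] - X.mean(0)) @ v.T
        assert np.allclose(np.abs(p_impl), np.abs(p_oracle), rtol=1e-6, atol=1e-9)

    def test_components_orthonormal(self):
        X = np.random.default_rng(8).normal(size=(50, 32))
        basis = ft.fit_waveform_basis(X, 8)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(8), atol=1e-8)

    def test_full_basis_reconstructs_exactly(self):
        X = np.random.default_rng(9).normal(size=(40, 32))
        basis = ft.fit_waveform_basis(X, 32)
        x = X[3]
        coeffs = ft.project_beat(x, basis)
        assert np.allclose(basis.mean_shape + coeffs @ basis.components, x, atol=1e-8)

    def test_reconstruction_error_nonincreasing_in_k(self):
        X = np.random.default_rng(10).normal(size=(40, 32))
        x = X[0]
        errs = []
        for k in (1, 2, 4, 8, 16):
            basis = ft.fit_waveform_basis(X, k)
            c = ft.project_beat(x, basis)
            errs.append(np.linalg.norm(basis.mean_shape + c @ basis.components - x))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_rank_deficiency_reported(self):
        X = np.tile(np.arange(32.0), (10, 1)) * np.arange(1, 11)[:, None]
        with pytest.raises(RankDeficiencyError, match="rank"):
            ft.fit_waveform_basis(X, 4)

    def test_mean_shape_projects_to_zero(self):
        X = np.random.default_rng(11).normal(size=(20, 32))
        basis = ft.fit_waveform_basis(X, 4)
        assert np.allclose(ft.project_beat(basis.mean_shape, basis), 0.0, atol=1e-10)

    def test_roundtrip_recovers_coefficients(self):
        X = np.random.default_rng(12).normal(size=(20, 32))
        basis = ft.fit_waveform_basis(X, 4)
        c = np.array([2.0, -1.0, 0.5, 3.0])
        shape = basis.mean_shape + c @ basis.components
        assert np.allclose(ft.project_beat(shape, basis), c, atol=1e-8)

    def test_save_load_roundtrip(self, tmp_path):
        X = np.random.default_rng(13).normal(size=(20, 32))
        basis = ft.fit_waveform_basis(X, 4)
        basis.save(tmp_path / "b.json")
        loaded = ft.WaveformBasis.load(tmp_path / "b.json")
        assert np.allclose(loaded.components, basis.components)
        assert np.allclose(loaded.mean_shape, basis.mean_shape)


class TestRatiosAndAssembly:
    def _sdptg(self, a, b, c, d, e):
        s = SDPTG(samples=np.array([a, b, c, d, e], float), a_idx=0, b_idx=1, c_idx=2, d_idx=3, e_idx=4)
        return s

    def test_ratio_arithmetic(self):
        sd = self._sdptg(2.0, -1.0, 0.4, -0.2, 0.1)
        assert ft.sdptg_ratios(sd) == pytest.approx((-0.5, 0.2, -0.1, 0.05))

    def test_zero_a_amp_rejected(self):
        with pytest.raises(FeatureAssemblyError):
            ft.sdptg_ratios(self._sdptg(0.0, -1.0, 0.4, -0.2, 0.1))

    def test_incomplete_rejected(self):
        sd = self._sdptg(2.0, -1.0, 0.4, -0.2, 0.1)
        sd.flags.add(FLAG_SDPTG_INCOMPLETE)
        with pytest.raises(FeatureAssemblyError):
            ft.sdptg_ratios(sd)

    def test_nineteen_elements_in_order(self):
        vec = ft.assemble_features(
            np.arange(4.0), np.arange(8.0), 72.0, (-0.5, 0.2, -0.1, 0.05), 7.0, 24.0
        )
        assert vec.shape == (19,)
        assert len(ft.FEATURE_NAMES) == 19
        assert vec[12] == 72.0 and vec[-2] == 7.0 and vec[-1] == 24.0

    def test_missing_si_dropped(self):
        with pytest.raises(FeatureAssemblyError):
            ft.assemble_features(np.arange(4.0), np.arange(8.0), 72.0, (-0.5, 0.2, -0.1, 0.05), None, 24.0)

    def test_non_finite_ratio_dropped(self):
        with pytest.raises(FeatureAssemblyError):
            ft.assemble_features(
                np.arange(4.0), np.arange(8.0), 72.0, (np.nan, 0.2, -0.1, 0.05), 7.0, 24.0
            )
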