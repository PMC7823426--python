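"""First-level features: HRF, task design, GLM, F maps, resting and VBM."""

import math

import numpy as np
import pytest
from scipy import integrate

from mlmfuse import (
    BlockParadigm,
    FContrast,
    build_task_design,
    canonical_hrf,
    fit_glm,
    omnibus_f_contrast,
    resting_feature_map,
    smooth_gaussian,
    task_feature_map,
    vbm_feature_map,
)
from .conftest import make_volume


def double_gamma(t):
    # closed form written out independently of the implementation
    return (
        t**5 * np.exp(-t) / math.factorial(5)
        - (t**15 * np.exp(-t) / math.factorial(15)) / 6.0
    )


class TestCanonicalHrf:
    def test_shape_peak_and_undershoot_timing(self):
        h = canonical_hrf(tr=2.0, length=32.0)
        assert len(h) == 16
        t = np.arange(16) * 2.0
        assert t[np.argmax(h)] == 6.0
        assert t[np.argmin(h)] == 16.0
        assert h[np.argmin(h)] < 0  # undershoot is real
        assert h.sum() > 0

    def test_sampling_consistency_across_tr(self):
        fine = canonical_hrf(tr=0.5, length=32.0)
        coarse = canonical_hrf(tr=2.0, length=32.0)
        assert np.allclose(fine[::4], coarse, atol=1e-12)

    def test_integral_matches_quadrature_of_closed_form(self):
        h = canonical_hrf(tr=0.1, length=32.0)
        riemann = np.trapezoid(h, dx=0.1)
        quad, _ = integrate.quad(double_gamma, 0.0, 31.9)
        assert np.isclose(riemann, quad, rtol=1e-3)

    def test_matches_spm_model_from_nilearn(self):
        # independent oracle: nilearn's SPM HRF (different sampling and
        # normalization, so compare shape via correlation)
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = canonical_hrf(tr=0.1, length=32.0)
        theirs = nilearn_hrf.spm_hrf(0.1, oversampling=1, time_length=32.0)
        # nilearn's time stamps sit half a frame later; align by one sample
        r = np.corrcoef(ours[:-1], theirs[1:])[0, 1]
        assert r > 0.999

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            canonical_hrf(tr=0.0)
        with pytest.raises(ValueError):
            canonical_hrf(tr=2.0, length=-1.0)


class TestBlockParadigm:
    def test_default_paradigm_timing(self):
        p = BlockParadigm.default_task()
        all_onsets = sorted(o for ons in p.onsets.values() for o in ons)
        assert len(all_onsets) == 12  # four blocks of each of three conditions
        gaps = np.diff(all_onsets)
        assert np.allclose(gaps, 52.0)  # 32 s active + 20 s rest
        assert p.onsets["DS"][0] == 0.0 and p.onsets["DN"][0] == 52.0
        assert all_onsets[-1] + p.duration <= p.n_volumes * p.tr

    def test_invalid_paradigms_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            BlockParadigm(onsets={"DS": [10.0, 5.0], "DN": [], "PS": []},
                          n_volumes=100)
        with pytest.raises(ValueError, match="beyond"):
            BlockParadigm(onsets={"DS": [190.0], "DN": [], "PS": []}, n_volumes=100)
        with pytest.raises(ValueError, match="tr"):
            BlockParadigm(tr=-2.0)


class TestTaskDesign:
    def test_column_counts(self, rng):
        p = BlockParadigm.default_task()
        assert build_task_design(p).values.shape[1] == 4  # 3 conditions + intercept
        motion = rng.normal(size=(p.n_volumes, 6)) * 0.01
        d = build_task_design(p, motion=motion)
        assert d.values.shape[1] == 10
        assert len(d.nuisance_columns) == 7  # 6 motion + intercept

    def test_condition_column_is_boxcar_convolved_with_hrf(self):
        # direct-convolution oracle built from the closed form
        p = BlockParadigm.default_task()
        d = build_task_design(p)
        t = np.arange(p.n_volumes) * p.tr
        box = np.zeros(p.n_volumes)
        for onset in p.onsets["DN"]:
            box[(t >= onset) & (t < onset + 32.0)] = 1.0
        kernel = double_gamma(np.arange(0, 32.0, p.tr))
        expected = np.convolve(box, kernel)[: p.n_volumes]
        assert np.allclose(d.values[:, 1], expected, atol=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        p = BlockParadigm.default_task()
        motion = np.ones((p.n_volumes, 6))  # constant, collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            build_task_design(p, motion=motion)

    def test_motion_shape_checked(self):
        p = BlockParadigm.default_task()
        with pytest.raises(ValueError, match="6"):
            build_task_design(p, motion=np.zeros((p.n_volumes, 5)))


def small_design(rng, n=60, with_motion=True):
    block, cycle = 10.0, 30.0
    onsets = {c: [i * cycle + k * block for i in range(2)]
              for k, c in enumerate(("DS", "DN", "PS"))}
    p = BlockParadigm(onsets=onsets, duration=8.0, rest_duration=2.0, n_volumes=n)
    motion = rng.normal(size=(n, 6)).cumsum(axis=0) * 0.01 if with_motion else None
    return build_task_design(p, motion=motion)


class TestFitGlm:
    def test_exact_beta_recovery_without_noise(self, rng):
        d = small_design(rng)
        b = rng.normal(size=(d.n_regressors, 7))
        fit = fit_glm(d.values @ b, d)
        assert np.allclose(fit.betas, b, atol=1e-10)
        assert np.allclose(fit.residual_variance, 0.0, atol=1e-10)
        assert fit.dof == d.n_volumes - d.n_regressors

    def test_residual_variance_is_unbiased_for_white_noise(self, rng):
        d = small_design(rng)
        sigma = 1.7
        n_vox = 4000
        fit = fit_glm(rng.normal(0, sigma, size=(d.n_volumes, n_vox)), d)
        # per-voxel RSS/dof ~ sigma^2 chi2(dof)/dof
        se = sigma**2 * np.sqrt(2.0 / fit.dof) / np.sqrt(n_vox)
        assert abs(fit.residual_variance.mean() - sigma**2) < 3 * se

    def test_degenerate_inputs_rejected(self, rng):
        d = small_design(rng, with_motion=False)
        with pytest.raises(ValueError, match="non-finite"):
            fit_glm(np.full((d.n_volumes, 2), np.nan), d)
        with pytest.raises(ValueError, match="volumes"):
            fit_glm(np.zeros((10, 2)), d)


class TestOmnibusContrast:
    def test_contrast_rows_count_and_motion_orthogonality(self, rng):
        d = small_design(rng)
        c = omnibus_f_contrast(d)
        assert c.k == 3
        tested = d.values @ c.contrast_rows.T  # design-space directions
        motion = d.values[:, d.nuisance_columns]
        assert np.max(np.abs(tested.T @ motion)) < 1e-10

    def test_orthogonal_design_gives_plain_selectors(self):
        # orthogonal toy design: conditions never overlap nuisance support
        X = np.zeros((12, 3))
        X[0:4, 0] = 1.0
        X[4:8, 1] = 1.0
        X[8:12, 2] = X[8:12, 2] + 1.0  # "intercept" orthogonal to conditions
        d_labels = ["A", "B", "intercept"]
        from mlmfuse import DesignMatrix

        d = DesignMatrix(X, d_labels, condition_columns=[0, 1], nuisance_columns=[2])
        c = omnibus_f_contrast(d)
        expected = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        assert np.allclose(c.contrast_rows, expected, atol=1e-12)

    def test_f_equals_reduced_model_extra_sum_of_squares(self, rng):
        # independent oracle: fit full and nuisance-only models and form the
        # classical extra-sum-of-squares F directly
        d = small_design(rng)
        y = rng.normal(size=(d.n_volumes, 50)) + d.values[:, :3] @ rng.normal(size=(3, 50))
        fit = fit_glm(y, d)
        f = task_feature_map(fit, omnibus_f_contrast(d))
        Xn = d.values[:, d.nuisance_columns]
        rss_full = np.sum((y - d.values @ np.linalg.lstsq(d.values, y, rcond=None)[0]) ** 2, axis=0)
        rss_red = np.sum((y - Xn @ np.linalg.lstsq(Xn, y, rcond=None)[0]) ** 2, axis=0)
        k, dof = 3, fit.dof
        expected = ((rss_red - rss_full) / k) / (rss_full / dof)
        assert np.allclose(f, expected, rtol=1e-8)

    def test_no_condition_columns_is_an_error(self):
        from mlmfuse import DesignMatrix

        d = DesignMatrix(np.ones((10, 1)), ["intercept"], [], [0])
        with pytest.raises(ValueError, match="condition"):
            omnibus_f_contrast(d)


class TestTaskFeatureMap:
    def test_null_f_mean_matches_f_distribution(self, rng):
        d = small_design(rng)
        fit = fit_glm(rng.normal(size=(d.n_volumes, 5000)), d)
        f = task_feature_map(fit, omnibus_f_contrast(d))
        k, dof = 3, fit.dof
        expected_mean = dof / (dof - 2)
        f_var = (2 * dof**2 * (k + dof - 2)) / (k * (dof - 2) ** 2 * (dof - 4))
        se = np.sqrt(f_var / 5000)
        assert abs(f.mean() - expected_mean) < 3 * se

    def test_planted_activation_beats_null_quantile(self, rng):
        d = small_design(rng)
        x = d.values[:, :3].sum(axis=1)
        y = rng.normal(size=(d.n_volumes, 2000))
        y[:, :20] += 10.0 * x[:, None]  # strong activation in 20 voxels
        f = task_feature_map(fit_glm(y, d), omnibus_f_contrast(d))
        null_99 = np.quantile(f[20:], 0.99)
        assert np.all(f[:20] > null_99)

    def test_single_condition_f_equals_squared_t(self, rng):
        onsets = {"DS": [0.0, 30.0], "DN": [], "PS": []}
        p = BlockParadigm(condition_names=("DS",), onsets=onsets, duration=10.0,
                          n_volumes=30)
        d = build_task_design(p)
        y = rng.normal(size=(30, 200))
        fit = fit_glm(y, d)
        c = omnibus_f_contrast(d)
        f = task_feature_map(fit, c)
        # classical identity: dropping one column from the full model gives
        # F equal to the squared t of that column's beta in the full model
        X = d.values
        cov = np.linalg.inv(X.T @ X)
        cvec = np.zeros(d.n_regressors)
        cvec[0] = 1.0
        t2 = (cvec @ fit.betas) ** 2 / (cvec @ cov @ cvec * fit.residual_variance)
        assert np.allclose(f, t2, rtol=1e-10)

    def test_invariant_to_nuisance_reparameterization(self, rng):
        d = small_design(rng)
        y = rng.normal(size=(d.n_volumes, 100))
        f1 = task_feature_map(fit_glm(y, d), omnibus_f_contrast(d))
        # invertibly remix the motion block
        from mlmfuse import DesignMatrix

        T = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        X2 = d.values.copy()
        X2[:, 3:9] = X2[:, 3:9] @ T
        d2 = DesignMatrix(X2, d.labels, d.condition_columns, d.nuisance_columns)
        f2 = task_feature_map(fit_glm(y, d2), omnibus_f_contrast(d2))
        assert np.allclose(f1, f2, rtol=1e-8)

    def test_effects_mode_returns_k_maps(self, rng):
        d = small_design(rng)
        y = rng.normal(size=(d.n_volumes, 10))
        eff = task_feature_map(fit_glm(y, d), omnibus_f_contrast(d), mode="effects")
        assert eff.shape == (3, 10)

    def test_zero_residual_variance_flagged_as_inf(self, rng):
        d = small_design(rng, with_motion=False)
        y = np.zeros((d.n_volumes, 3))  # residuals exactly zero
        fit = fit_glm(y, d)
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            f = task_feature_map(fit, omnibus_f_contrast(d))
        assert np.all(np.isinf(f))

    def test_linearly_dependent_contrast_rows_rejected(self):
        with pytest.raises(ValueError, match="independent"):
            FContrast(np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestRestingFeatureMap:
    def test_constant_series_gives_zero(self):
        series = np.full((50, 4), 7.0)
        assert np.allclose(resting_feature_map(series), 0.0, atol=1e-20)

    def test_invariant_to_adding_a_constant(self, rng):
        series = rng.normal(size=(60, 30))
        a = resting_feature_map(series)
        b = resting_feature_map(series + 123.4)
        assert np.allclose(a, b, atol=1e-8)

    def test_recovers_noise_variance(self, rng):
        sigma = 2.5
        n, v = 120, 3000
        rms = resting_feature_map(rng.normal(0, sigma, size=(n, v)))
        se = sigma**2 * np.sqrt(2.0 / (n - 1)) / np.sqrt(v)
        assert abs(rms.mean() - sigma**2) < 3 * se

    def test_motion_regression_reduces_residual(self, rng):
        n = 80
        motion = rng.normal(size=(n, 6)).cumsum(axis=0) * 0.1
        series = 5.0 + motion[:, [0]] * 3.0 + rng.normal(0, 0.5, size=(n, 1))
        with_motion = resting_feature_map(series, motion=motion)
        without = resting_feature_map(series)
        assert with_motion[0] < without[0]


class TestVbmFeatureMap:
    def test_zero_fwhm_identity_and_absent_tiv(self, rng):
        gm = make_volume(np.abs(rng.normal(size=(5, 5, 5))))
        out, tiv = vbm_feature_map(gm, fwhm_mm=0.0)
        assert np.array_equal(out.data, gm.data)
        assert tiv is None

    def test_tiv_from_three_constant_tissue_maps(self):
        maps = [make_volume(np.full((10, 10, 10), 1.0 / 3.0), voxel=2.0)
                for _ in range(3)]
        _, tiv = vbm_feature_map(maps[0], fwhm_mm=0.0, tissue_maps=maps)
        assert np.isclose(tiv, 8.0)  # 8 mm^3 x 1000 voxels = 8 ml

    def test_smoothing_delegates_bit_exactly(self, rng):
        gm = make_volume(np.abs(rng.normal(size=(6, 6, 6))), voxel=2.0)
        out, _ = vbm_feature_map(gm, fwhm_mm=8.0)
        assert np.array_equal(out.data, smooth_gaussian(gm, 8.0).data)

    def test_negative_gm_rejected(self):
        gm = make_volume(np.full((3, 3, 3), -0.1))
        with pytest.raises(ValueError, match="negative"):
            vbm_feature_map(gm)
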