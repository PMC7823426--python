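"""Stage-1 MLM: design building, decomposition and scores."""

import numpy as np
import pandas as pd
import pytest

from mlmfuse import (
    MLM,
    MLMDesign,
    build_mlm_design,
    correlation_map,
    fit_mlm,
    informative_components,
)


def frame(groups, ages=None, sexes=None, tivs=None):
    n = len(groups)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": groups,
            "age": ages if ages is not None else np.linspace(25, 60, n),
            "sex": sexes if sexes is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "tiv": tivs if tivs is not None else np.linspace(1300, 1700, n),
        }
    )


def intercept_design(groups):
    g = np.where(np.asarray(groups) == groups[0], 1.0, -1.0)
    return MLMDesign(g, np.ones((len(groups), 1)), (groups[0], groups[1] if groups[1] != groups[0] else [x for x in groups if x != groups[0]][0]))


class TestBuildDesign:
    def test_shapes_and_column_order(self):
        d = build_mlm_design(frame(["A", "A", "B", "B"]), covariates=("age",))
        assert d.nuisance.shape == (4, 2)
        assert d.nuisance_labels == ["intercept", "age"]
        full = build_mlm_design(frame(["A", "A", "B", "B", "A", "B"]),
                                covariates=("age", "sex", "tiv"))
        assert full.nuisance.shape == (6, 4)

    def test_continuous_covariates_are_z_scored(self):
        d = build_mlm_design(frame(["A"] * 5 + ["B"] * 5), covariates=("age", "tiv"))
        for j in (1, 2):
            col = d.nuisance[:, j]
            assert abs(col.mean()) < 1e-12
            assert abs(col.std() - 1.0) < 1e-12

    def test_group_coding_follows_group_order(self):
        df = frame(["B", "A", "A", "B"])
        d = build_mlm_design(df, covariates=(), group_order=("A", "B"))
        assert np.array_equal(d.group_indicator, [-1, 1, 1, -1])

    def test_missing_covariate_names_subject(self):
        df = frame(["A", "A", "B", "B"])
        df.loc[2, "age"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            build_mlm_design(df, covariates=("age",))

    def test_single_level_group_rejected(self):
        with pytest.raises(ValueError, match="one group"):
            build_mlm_design(frame(["A", "A", "A", "A"]), covariates=())

    def test_group_confounded_with_nuisance_rejected(self):
        # nuisance contains the group indicator itself
        g = np.array([1.0, 1, -1, -1])
        nuis = np.column_stack([np.ones(4), g])
        design = MLMDesign(g, nuis, ("A", "B"))
        with pytest.raises(ValueError, match="confounded"):
            fit_mlm(np.random.default_rng(0).normal(size=(4, 5)), design)


class TestFitMlm:
    def test_noise_free_eigen_image_is_group_difference_pattern(self, rng):
        pattern = rng.normal(size=30)
        Y = np.vstack([np.tile(pattern, (4, 1)), np.tile(-pattern, (4, 1))])
        design = build_mlm_design(frame(["A"] * 4 + ["B"] * 4), covariates=())
        res = fit_mlm(Y, design)
        v = res.eigen_images[0]
        p = pattern / np.linalg.norm(pattern)
        assert min(np.linalg.norm(v - p), np.linalg.norm(v + p)) < 1e-8
        assert res.n_informative == 1

    def test_identical_subjects_give_null_result(self):
        Y = np.tile(np.arange(12.0), (6, 1))
        design = build_mlm_design(frame(["A"] * 3 + ["B"] * 3), covariates=())
        res = fit_mlm(Y, design)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-18)
        assert res.n_informative == 0
        assert np.allclose(res.variance_fractions, 0.0)

    def test_two_group_contrast_rank_bound(self, rng):
        Y = rng.normal(size=(10, 50))
        design = build_mlm_design(frame(["A"] * 5 + ["B"] * 5))
        res = fit_mlm(Y, design)
        assert res.n_components == 1
        assert res.n_informative <= 1

    def test_eigen_image_invariant_to_nuisance_shifts(self, rng):
        df = frame(["A"] * 6 + ["B"] * 6)
        design = build_mlm_design(df, covariates=("age", "sex", "tiv"))
        Y = rng.normal(size=(12, 40))
        base = fit_mlm(Y, design)
        # add arbitrary voxel patterns carried by nuisance columns
        shift = design.nuisance @ rng.normal(size=(4, 40)) * 5.0
        shifted = fit_mlm(Y + shift, design)
        assert np.allclose(base.eigen_images, shifted.eigen_images, atol=1e-8)
        assert np.allclose(base.eigenvalues, shifted.eigenvalues, rtol=1e-8)

    def test_sign_convention_first_group_positive_prediction(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            Y = r.normal(size=(8, 20)) + np.outer(
                np.repeat([1.0, -1.0], 4), r.normal(size=20)
            )
            design = build_mlm_design(frame(["A"] * 4 + ["B"] * 4), covariates=())
            res = fit_mlm(Y, design)
            assert res.predicted_scores[:4, 0].mean() >= 0

    def test_empirical_scores_are_projections_of_adjusted_data(self, rng):
        Y = rng.normal(size=(10, 30))
        design = build_mlm_design(frame(["A"] * 5 + ["B"] * 5), covariates=("age",))
        res = fit_mlm(Y, design)
        assert np.allclose(
            res.empirical_scores[:, 0], res.adjusted_data @ res.eigen_images[0]
        )

    def test_planted_pattern_recovery_at_study_conditions(self):
        # n = 20 per group, effect amplitude 1.0, noise sd 1.0; the pattern
        # carries enough energy for recovery: expected |corr| is about
        # sqrt(S / (S + 0.1 V)) with S = ||p||^2, here about 0.89
        pattern = np.zeros(400)
        pattern[:300] = np.linspace(1.0, 0.4, 300)
        p_unit = pattern / np.linalg.norm(pattern)
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            g = np.repeat([0.5, -0.5], 20)
            Y = np.outer(g, pattern) + r.normal(size=(40, 400))
            design = build_mlm_design(frame(["A"] * 20 + ["B"] * 20), covariates=())
            res = fit_mlm(Y, design)
            if abs(np.dot(res.eigen_images[0], p_unit)) >= 0.8:
                hits += 1
        assert hits >= 4

    def test_standardize_flag_changes_scale_not_validity(self, rng):
        Y = rng.normal(size=(10, 25)) * np.linspace(1, 50, 25)
        design = build_mlm_design(frame(["A"] * 5 + ["B"] * 5), covariates=())
        res = fit_mlm(Y, design, standardize=True)
        assert np.isclose(np.linalg.norm(res.eigen_images[0]), 1.0, atol=1e-10)

    def test_summary_and_scores_frame(self, rng):
        Y = rng.normal(size=(8, 15))
        design = build_mlm_design(frame(["A"] * 4 + ["B"] * 4), covariates=("age",))
        res = fit_mlm(Y, design)
        text = res.summary()
        assert "eigenvalue" in text and "A" in text
        sf = res.scores_frame()
        assert list(sf.columns) == ["subject_id", "group", "empirical", "predicted"]


class TestInformativeComponents:
    @pytest.mark.parametrize(
        "eigenvalues,expected",
        [((5.0, 3.0, 2.0), 3), ((5.0, 0.0, 0.0), 1), ((0.0, 0.0, 0.0), 0),
         ((1.0, 1e-12), 1), ((), 0)],
    )
    def test_counting_rules(self, eigenvalues, expected):
        assert informative_components(list(eigenvalues)) == expected

    def test_requires_descending_nonnegative(self):
        with pytest.raises(ValueError):
            informative_components([1.0, 2.0])
        with pytest.raises(ValueError):
            informative_components([1.0, -0.5])


class TestCorrelationMap:
    def test_perfectly_correlated_voxels(self, rng):
        s = rng.normal(size=10)
        Y = np.column_stack([s, -s, rng.normal(size=10)])
        corr = correlation_map(Y, s)
        assert np.isclose(corr[0], 1.0)
        assert np.isclose(corr[1], -1.0)
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)

    def test_matches_textbook_formula(self, rng):
        Y = rng.normal(size=(44, 25))
        s = rng.normal(size=44)
        corr = correlation_map(Y, s)
        expected = [np.corrcoef(Y[:, j], s)[0, 1] for j in range(25)]
        assert np.allclose(corr, expected, atol=1e-12)

    def test_zero_variance_voxel_flagged(self, rng):
        Y = np.column_stack([np.full(8, 3.0), rng.normal(size=8)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            corr = correlation_map(Y, rng.normal(size=8))
        assert corr[0] == 0.0

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            correlation_map(rng.normal(size=(6, 4)), np.ones(6))


def test_mlm_rejects_misaligned_or_nonfinite_input(rng):
    design = build_mlm_design(frame(["A"] * 4 + ["B"] * 4), covariates=())
    with pytest.raises(ValueError, match="rows"):
        MLM(rng.normal(size=(5, 10)), design)
    bad = rng.normal(size=(8, 10))
    bad[0, 0] = np.inf
    with pytest.raises(ValueError, match="finite"):
        MLM(bad, design)
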