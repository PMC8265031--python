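"""Local surrogate (LIME) machinery: standardization, permutations,
weighting, surrogate fits."""

import numpy as np
import pandas as pd
import pytest

from knnexplain import (
    InputError,
    LimeExplainer,
    PermutationSet,
    PreconditionError,
    SubsetKNNClassifier,
    destandardize,
    estimate_standardization,
    fit_surrogate,
    generate_permutations,
    standardize,
    weight_permutations,
)


class TestStandardization:
    def test_median_maps_to_zero(self, refs):
        X, _ = refs
        params = estimate_standardization(X)
        x = np.exp(params.median)
        np.testing.assert_allclose(standardize(x, params), 0.0, atol=1e-12)

    def test_one_scale_above_median_maps_to_one(self, refs):
        X, _ = refs
        params = estimate_standardization(X)
        x = np.exp(params.median + params.scale)
        np.testing.assert_allclose(standardize(x, params), 1.0, atol=1e-12)

    def test_round_trip(self, refs):
        X, _ = refs
        params = estimate_standardization(X)
        x = X.iloc[3].to_numpy()
        np.testing.assert_allclose(destandardize(standardize(x, params), params), x, rtol=1e-12)

    def test_scale_is_iqr_over_1_35(self, refs):
        X, _ = refs
        params = estimate_standardization(X)
        logX = np.log(X.to_numpy())
        iqr = np.percentile(logX, 75, axis=0) - np.percentile(logX, 25, axis=0)
        np.testing.assert_allclose(params.scale, iqr / 1.35, rtol=1e-12)

    def test_non_positive_rejected(self, refs):
        X, _ = refs
        params = estimate_standardization(X)
        with pytest.raises(InputError):
            standardize(np.full(8, -1.0), params)


class TestPermutations:
    def test_total_count_is_twice_per_class(self, refs):
        X, y = refs
        perms = generate_permutations(X, y, n_per_class=500, seed=0)
        assert len(perms.X) == 1000
        assert (perms.source_class == 1).sum() == 500
        assert (perms.source_class == -1).sum() == 500

    def test_discard_rule_is_exact(self, refs):
        """kept <=> the full 7NN classification equals the source class,
        re-derived independently for every permutation."""
        X, y = refs
        perms = generate_permutations(X, y, n_per_class=400, seed=1)
        clf = SubsetKNNClassifier().fit(X, y)
        reclassified = clf.predict(perms.X)
        np.testing.assert_array_equal(perms.kept, reclassified == perms.source_class)

    def test_separated_classes_discard_near_zero(self, refs):
        X, y = refs  # default spec: well-separated classes
        perms = generate_permutations(X, y, n_per_class=2000, seed=2)
        assert perms.discard_fraction < 0.05

    def test_seeded_rerun_is_identical(self, refs):
        X, y = refs
        a = generate_permutations(X, y, n_per_class=300, seed=9)
        b = generate_permutations(X, y, n_per_class=300, seed=9)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.classification, b.classification)

    def test_tiny_count_rejected(self, refs):
        X, y = refs
        with pytest.raises(InputError, match="too small"):
            generate_permutations(X, y, n_per_class=10, seed=0)


class TestWeights:
    def test_kernel_formula_and_bounds(self, refs):
        X, y = refs
        perms = generate_permutations(X, y, n_per_class=500, seed=3)
        params = estimate_standardization(X)
        x = X.iloc[0].to_numpy()
        w, sigma = weight_permutations(perms, x, params)
        # recompute distances independently
        Zk = np.vstack([standardize(row, params) for row in perms.X[perms.kept]])
        d = np.linalg.norm(Zk - standardize(x, params), axis=1)
        assert sigma == pytest.approx(d.mean())
        np.testing.assert_allclose(w, np.exp(-(d ** 2) / sigma ** 2), rtol=1e-12)
        assert np.all((w > 0) & (w <= 1))

    def test_zero_distance_gives_weight_one(self, refs):
        X, y = refs
        perms = generate_permutations(X, y, n_per_class=500, seed=3)
        params = estimate_standardization(X)
        x = perms.X[perms.kept][10]  # explain a kept permutation itself
        w, _ = weight_permutations(perms, x, params)
        assert w[10] == pytest.approx(1.0)
        assert w.max() == pytest.approx(1.0)

    def test_half_mean_rule_shrinks_weights(self, refs):
        X, y = refs
        perms = generate_permutations(X, y, n_per_class=500, seed=3)
        params = estimate_standardization(X)
        x = X.iloc[0].to_numpy()
        w_mean, s_mean = weight_permutations(perms, x, params, "mean_distance")
        w_half, s_half = weight_permutations(perms, x, params, "half_mean_distance")
        assert s_half == pytest.approx(0.5 * s_mean)
        positive_d = w_mean < 1.0
        assert np.all(w_half[positive_d] < w_mean[positive_d])


class TestSurrogates:
    def test_informative_feature_dominates(self, single_feature_refs):
        """Classes separated along feature 0 only: the surrogate coefficient
        for feature 0 dominates and is positive (higher value -> Good)."""
        X, y = single_feature_refs
        for surrogate in ("logistic", "linear_svm"):
            attr = (
                LimeExplainer(surrogate=surrogate, n_per_class=4000, random_state=1)
                .fit(X, y)
                .explain_one(X.iloc[0].to_numpy())
            )
            assert attr.phi[0] > 0
            assert abs(attr.phi[0]) > 3 * np.abs(attr.phi[1:]).max()

    def test_label_flip_negates_coefficients(self, single_feature_refs):
        X, y = single_feature_refs
        explainer = LimeExplainer(surrogate="logistic", n_per_class=2000, random_state=4).fit(X, y)
        x = X.iloc[0].to_numpy()
        attr = explainer.explain_one(x)
        perms = explainer.permutations_
        flipped = PermutationSet(
            feature_names=perms.feature_names,
            X=perms.X,
            source_class=-perms.source_class,
            classification=-perms.classification,
            seed=perms.seed,
        )
        w, _ = weight_permutations(flipped, x, explainer.params_)
        attr_flipped = fit_surrogate(flipped, w, explainer.params_, model_kind="logistic")
        np.testing.assert_allclose(attr_flipped.phi, -attr.phi, atol=1e-4)

    def test_duplicated_permutations_leave_fit_unchanged(self, single_feature_refs):
        X, y = single_feature_refs
        explainer = LimeExplainer(surrogate="logistic", n_per_class=1000, random_state=5).fit(X, y)
        x = X.iloc[1].to_numpy()
        perms = explainer.permutations_
        doubled = PermutationSet(
            feature_names=perms.feature_names,
            X=np.vstack([perms.X, perms.X]),
            source_class=np.concatenate([perms.source_class] * 2),
            classification=np.concatenate([perms.classification] * 2),
            seed=perms.seed,
        )
        w1, _ = weight_permutations(perms, x, explainer.params_)
        w2, _ = weight_permutations(doubled, x, explainer.params_)
        a1 = fit_surrogate(perms, w1, explainer.params_, model_kind="logistic")
        a2 = fit_surrogate(doubled, w2, explainer.params_, model_kind="logistic")
        np.testing.assert_allclose(a1.phi, a2.phi, atol=1e-5)

    def test_single_class_permutations_rejected(self, single_feature_refs):
        X, y = single_feature_refs
        explainer = LimeExplainer(surrogate="logistic", n_per_class=500, random_state=6).fit(X, y)
        perms = explainer.permutations_
        all_good = PermutationSet(
            feature_names=perms.feature_names,
            X=perms.X,
            source_class=np.ones_like(perms.source_class),
            classification=np.ones_like(perms.classification),
            seed=perms.seed,
        )
        w = np.ones(int(all_good.kept.sum()))
        with pytest.raises(PreconditionError, match="both"):
            fit_surrogate(all_good, w, explainer.params_, model_kind="logistic")

    def test_feature_rescaling_leaves_coefficients_unchanged(self, single_feature_refs):
        """Multiplying one feature's raw intensities by a constant shifts
        its log-median but not the standardized problem."""
        X, y = single_feature_refs
        x = X.iloc[2].to_numpy()
        a = (
            LimeExplainer(surrogate="logistic", n_per_class=2000, random_state=7)
            .fit(X, y)
            .explain_one(x)
        )
        X_scaled = X.copy()
        X_scaled["f2"] *= 10.0
        x_scaled = x.copy()
        x_scaled[2] *= 10.0
        b = (
            LimeExplainer(surrogate="logistic", n_per_class=2000, random_state=7)
            .fit(X_scaled, y)
            .explain_one(x_scaled)
        )
        np.testing.assert_allclose(a.phi, b.phi, rtol=1e-6, atol=1e-8)

    def test_unseeded_fit_refused(self, single_feature_refs):
        X, y = single_feature_refs
        with pytest.raises(PreconditionError, match="random_state"):
            LimeExplainer().fit(X, y)
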