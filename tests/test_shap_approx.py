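"""SHAP approximations: expectation tables, conditioning, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from knnexplain import (
    Attribution,
    CohortSpec,
    CopulaShapExplainer,
    EmpiricalMargin,
    GaussianShapExplainer,
    KernelShapExplainer,
    PreconditionError,
    SubsetKNNClassifier,
    approx_shapley,
    compare_to_exact,
    fit_distribution,
    make_reference_set,
    make_uniform_instance,
)


@pytest.fixture(scope="module")
def instance(refs):
    X, y = refs
    return make_uniform_instance(X, y, "Good").to_numpy()


# ----------------------------------------------------------------- kernel
class TestKernelShap:
    def naive_expectation(self, x, X, y_codes, subset_idx, k=7):
        """Independent oracle: build each hybrid by hand, classify it by
        its own sorted log-distance majority vote over all features."""
        results = []
        for r in range(len(X)):
            hybrid = X[r].copy()
            hybrid[subset_idx] = x[subset_idx]
            d = [
                sum((np.log(hybrid[i]) - np.log(X[s, i])) ** 2 for i in range(X.shape[1]))
                for s in range(len(X))
            ]
            order = sorted(range(len(d)), key=lambda s: (d[s], s))[:k]
            votes = sum(y_codes[s] for s in order)
            results.append(1 if votes > 0 else -1)
        return float(np.mean(results))

    def test_expectation_table_matches_naive_hybrids(self):
        rng = np.random.default_rng(8)
        X = np.exp(rng.normal(0, 1, size=(10, 4)))
        y = np.array([1] * 5 + [-1] * 5)
        x = np.exp(rng.normal(0, 1, size=4))
        explainer = KernelShapExplainer(k=3).fit(X, y)
        table = explainer.expectation_table(x)
        for mask in range(15):  # all proper subsets
            idx = [i for i in range(4) if mask >> i & 1]
            assert table.values[mask] == pytest.approx(
                self.naive_expectation(x, X, y, idx, k=3), abs=1e-12
            )

    def test_full_subset_is_own_classification(self, refs, instance):
        X, y = refs
        explainer = KernelShapExplainer().fit(X, y)
        table = explainer.expectation_table(instance)
        assert table.full_value == SubsetKNNClassifier().fit(X, y).predict(instance)[0]

    def test_identical_feature_gets_zero(self):
        """A feature shared by the instance and all references never changes
        a hybrid, so its kernel-SHAP value is 0."""
        rng = np.random.default_rng(9)
        X = np.exp(rng.normal(0, 1, size=(10, 4)))
        X[:, 2] = 7.0
        y = [1] * 5 + [-1] * 5
        x = np.exp(rng.normal(0, 1, size=4))
        x[2] = 7.0
        attr = KernelShapExplainer(k=3).fit(X, y).explain_one(x)
        assert attr.phi[2] == 0.0

    def test_deterministic(self, refs, instance):
        X, y = refs
        e = KernelShapExplainer().fit(X, y)
        np.testing.assert_array_equal(e.explain_one(instance).phi, e.explain_one(instance).phi)

    def test_efficiency(self, refs, instance):
        X, y = refs
        a = KernelShapExplainer().fit(X, y).explain_one(instance)
        assert a.phi.sum() + a.null_value == pytest.approx(a.full_value, abs=1e-12)


# --------------------------------------------------------------- gaussian
class TestGaussianShap:
    def test_unseeded_rng_refused(self, refs, instance):
        X, y = refs
        with pytest.raises(PreconditionError, match="seed"):
            GaussianShapExplainer().fit(X, y).explain_one(instance)

    def test_full_subset_needs_no_sampling(self, refs, instance):
        X, y = refs
        e = GaussianShapExplainer(random_state=0).fit(X, y)
        names = e.classifier_.feature_names_
        assert e.conditional_expectation(instance, names) == SubsetKNNClassifier().fit(
            X, y
        ).predict(instance)[0]

    def test_seed_determinism(self, refs, instance):
        X, y = refs
        a = GaussianShapExplainer(random_state=7).fit(X, y).explain_one(instance)
        b = GaussianShapExplainer(random_state=7).fit(X, y).explain_one(instance)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_null_expectation_vs_quadrature(self):
        """Unconditional (empty-subset) expectation on a 2-feature diagonal
        Gaussian matches dense quadrature over the fitted density."""
        rng = np.random.default_rng(4)
        X = np.exp(np.column_stack([rng.normal(0, 0.5, 400), rng.normal(2, 0.5, 400)]))
        y = [1, -1] * 200
        # labels alternate so the classifier is noisy; only the expectation
        # machinery is under test
        e = GaussianShapExplainer(n_samples=40000, random_state=1, k=3).fit(X, y)
        mc = e.conditional_expectation(np.exp([0.0, 2.0]), [])
        mu, cov = e.model_.location, e.model_.covariance
        gx, gy = np.meshgrid(
            np.linspace(mu[0] - 4, mu[0] + 4, 120), np.linspace(mu[1] - 4, mu[1] + 4, 120)
        )
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        from scipy.stats import multivariate_normal

        w = multivariate_normal(mu, cov).pdf(pts)
        preds = e.classifier_.predict_coords(pts)
        quad = float(np.sum(w * preds) / np.sum(w))
        assert mc == pytest.approx(quad, abs=0.03)

    def test_perfect_correlation_conditions_on_regression_line(self):
        """With a perfectly correlated pair, sampling i | j concentrates at
        the regression prediction (closed-form bivariate conditional)."""
        from knnexplain.shap_approx import _conditional_gaussian

        mu = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.999], [0.999, 1.0]])
        mean, cov_out = _conditional_gaussian(mu, cov, idx_in=[1], idx_out=[0], x_in=np.array([0.0]))
        # closed form: mu0 + rho*(x1 - mu1), var (1 - rho^2)
        assert mean[0] == pytest.approx(1.0 + 0.999 * (0.0 - (-2.0)), abs=1e-12)
        assert cov_out[0, 0] == pytest.approx(1 - 0.999 ** 2, abs=1e-12)

    def test_monte_carlo_variance_shrinks_with_n(self):
        spec = CohortSpec(seed=7, feature_names=("a", "b", "c", "d"))
        X, y = make_reference_set(spec)
        x = make_uniform_instance(X, y, "Good").to_numpy() * np.exp(-0.8)
        variances = {}
        for n in (100, 1000):
            phis = [
                GaussianShapExplainer(n_samples=n, random_state=1000 + s)
                .fit(X, y)
                .explain_one(x)
                .phi
                for s in range(20)
            ]
            variances[n] = float(np.vstack(phis).var(axis=0).mean())
        assert variances[100] > 0
        assert 3.0 < variances[100] / variances[1000] < 30.0


# ----------------------------------------------------------------- copula
class TestCopulaShap:
    def test_margin_round_trip(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=26)
        margin = EmpiricalMargin(v)
        np.testing.assert_allclose(
            margin.inverse(margin.pit(margin.values)), margin.values, atol=1e-9
        )

    def test_margin_monotone_and_defined_everywhere(self):
        margin = EmpiricalMargin(np.random.default_rng(1).normal(size=26))
        # strictly monotone wherever the CDF is representable in floats
        lo = margin.values[0] - 3 * margin.lam_lo
        hi = margin.values[-1] + 3 * margin.lam_hi
        u = margin.pit(np.linspace(lo, hi, 500))
        assert np.all(np.diff(u) > 0)
        x = margin.inverse(np.linspace(1e-9, 1 - 1e-9, 500))
        assert np.all(np.diff(x) > 0)

    def test_seed_determinism(self, refs, instance):
        X, y = refs
        a = CopulaShapExplainer(random_state=3).fit(X, y).explain_one(instance)
        b = CopulaShapExplainer(random_state=3).fit(X, y).explain_one(instance)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_full_subset_exact(self, refs, instance):
        X, y = refs
        e = CopulaShapExplainer(random_state=0).fit(X, y)
        table = e.expectation_table(instance)
        assert table.full_value == SubsetKNNClassifier().fit(X, y).predict(instance)[0]


# --------------------------------------------------------- distribution fit
class TestFitDistribution:
    def test_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(3)
        cov_true = CohortSpec().covariance()
        L = np.linalg.cholesky(cov_true)
        X = np.exp(5.0 + rng.standard_normal((10_000, 8)) @ L.T)
        model = fit_distribution(X, "multivariate_gaussian")
        assert np.abs(model.covariance - cov_true).max() < 0.02
        assert np.abs(model.location - 5.0).max() < 0.05

    def test_collinear_features_raise_without_shrinkage(self):
        rng = np.random.default_rng(5)
        X = np.exp(rng.normal(0, 1, size=(26, 3)))
        X = np.column_stack([X, X[:, 0]])  # duplicated feature
        with pytest.raises(PreconditionError, match="shrinkage"):
            fit_distribution(X, "multivariate_gaussian", shrinkage=0.0)
        # correlation of the duplicated pair is 1 before regularization
        logX = np.log(X)
        assert np.corrcoef(logX[:, 0], logX[:, 3])[0, 1] == pytest.approx(1.0)

    def test_independent_reference_has_no_parameters(self, refs):
        X, _ = refs
        model = fit_distribution(X, "independent_reference")
        assert model.location is None and model.covariance is None


# ------------------------------------------------------------- comparison
class TestCompareToExact:
    names = ("a", "b", "c")

    def _attr(self, method, phi, iid="s0"):
        return Attribution(iid, method, self.names, np.asarray(phi, float), 0.0, 1.0)

    def test_identity_msd_zero(self):
        exact = [self._attr("exact", [0.1, 0.2, 0.7])]
        approx = [self._attr("kernel_shap", [0.1, 0.2, 0.7])]
        assert compare_to_exact(approx, exact)["msd"] == 0.0

    def test_constant_offset_msd(self):
        exact = [self._attr("exact", [0.1, 0.2, 0.7])]
        approx = [self._attr("kernel_shap", [0.2, 0.3, 0.8])]
        assert compare_to_exact(approx, exact)["msd"] == pytest.approx(0.01)

    def test_instance_mismatch_rejected(self):
        with pytest.raises(PreconditionError):
            compare_to_exact(
                [self._attr("kernel_shap", [0, 0, 0], iid="s1")],
                [self._attr("exact", [0, 0, 0], iid="s2")],
            )

    def test_symmetry_violation_detected(self, uniform_good_table):
        """On a uniform table every pair has equal subset behavior, so any
        unequal approximate values are flagged as symmetry violations."""
        names = uniform_good_table.feature_names
        exact = [
            Attribution("u", "exact", names, np.full(8, 0.125), 0.0, 1.0)
        ]
        phi = np.full(8, 0.125)
        phi[0] += 0.05
        approx = [Attribution("u", "kernel_shap", names, phi, 0.0, 1.0)]
        report = compare_to_exact(approx, exact, symmetry_tables={"u": uniform_good_table})
        pairs = {(v["feature_i"], v["feature_j"]) for v in report["symmetry_violations"]}
        assert len(pairs) == 7  # feature 0 against each of the other seven
        assert all(names[0] in p for p in pairs)

    def test_approx_shapley_dispatch(self, refs, instance):
        X, y = refs
        a = approx_shapley(instance, X, y, kind="independent_reference")
        b = KernelShapExplainer().fit(X, y).explain_one(instance)
        np.testing.assert_array_equal(a.phi, b.phi)
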