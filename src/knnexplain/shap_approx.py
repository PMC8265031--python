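"""Shapley-value approximations that avoid subset retraining.

Instead of restricting the classifier to each feature subset S, these
methods keep the full-feature classifier and replace f(S) in the Shapley
sum by a conditional expectation of the full prediction given the in-S
feature values.  Three feature-distribution assumptions of increasing
fidelity are provided:

* ``kernel_shap`` — features independent; the expectation for S averages
  the full classification of hybrids in which out-of-S features are
  replaced by each reference sample's values in turn (26 hybrids per
  subset).  Fully deterministic.
* ``gaussian_shap`` — log features jointly Gaussian, parameters estimated
  from the reference set; out-of-S features are drawn from the exact
  Gaussian conditional given the in-S values (N Monte-Carlo draws per
  subset, default 1000).
* ``copula_shap`` — arbitrary margins coupled by a Gaussian copula:
  per-feature empirical probability-integral transform (PIT) to Gaussian
  scores, conditioning in score space, inverse PIT back before
  classification.

The expectation for the empty subset is computed by the same machinery
(everything replaced/unconditioned), not forced to 0; for a balanced,
self-consistent reference set it is close to the exact convention f(∅)=0.
All expectations are computed over the full 2**m subset lattice and plugged
into the exact Shapley weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .attribution import Attribution
from .errors import InputError, PreconditionError
from .knn import SubsetKNNClassifier
from .shapley import shapley_values
from .tables import SubsetValueTable

DISTRIBUTION_KINDS = ("independent_reference", "multivariate_gaussian", "gaussian_copula")


# --------------------------------------------------------------------------
# empirical margins for the copula
# --------------------------------------------------------------------------
class EmpiricalMargin:
    """Piecewise-linear empirical CDF of one feature (log scale) with
    exponential tails.

    Sorted observations v_1..v_n carry plotting positions p_i = i/(n+1);
    the CDF interpolates linearly between them and decays exponentially
    beyond the observed range (tail scales taken from the extreme
    spacings), so the PIT and its inverse are defined and strictly
    monotone on the whole real line.
    """

    def __init__(self, values: np.ndarray):
        v = np.sort(np.asarray(values, dtype=float))
        if v.size < 2:
            raise InputError("empirical margin needs at least two observations")
        scale = max(float(v[-1] - v[0]), 1e-12)
        # deterministic tiebreak keeps the CDF strictly increasing
        v = v + np.arange(v.size) * (1e-9 * scale / v.size)
        n = v.size
        self.values = v
        self.probs = np.arange(1, n + 1) / (n + 1.0)
        self.lam_lo = max(float(v[1] - v[0]), 1e-6 * scale)
        self.lam_hi = max(float(v[-1] - v[-2]), 1e-6 * scale)

    def pit(self, x) -> np.ndarray:
        """Probability integral transform to (0, 1)."""
        x = np.asarray(x, dtype=float)
        u = np.interp(x, self.values, self.probs)
        lo = x < self.values[0]
        hi = x > self.values[-1]
        u = np.where(lo, self.probs[0] * np.exp((x - self.values[0]) / self.lam_lo), u)
        u = np.where(
            hi,
            1.0 - (1.0 - self.probs[-1]) * np.exp(-(x - self.values[-1]) / self.lam_hi),
            u,
        )
        return np.clip(u, 1e-12, 1.0 - 1e-12)

    def inverse(self, u) -> np.ndarray:
        """Inverse PIT; defined for all u in (0, 1)."""
        u = np.clip(np.asarray(u, dtype=float), 1e-12, 1.0 - 1e-12)
        x = np.interp(u, self.probs, self.values)
        lo = u < self.probs[0]
        hi = u > self.probs[-1]
        x = np.where(lo, self.values[0] + self.lam_lo * np.log(u / self.probs[0]), x)
        x = np.where(
            hi,
            self.values[-1] - self.lam_hi * np.log((1.0 - u) / (1.0 - self.probs[-1])),
            x,
        )
        return x


@dataclass
class DistributionModel:
    """Fitted feature-distribution model for conditional expectations.

    ``location``/``covariance`` live in log-feature space for the Gaussian
    kind and in Gaussian-score space (zero location, correlation-like
    covariance) for the copula kind; ``margins`` are per-feature empirical
    CDFs of log intensity, present only for the copula.
    """

    kind: str
    feature_names: tuple[str, ...]
    location: np.ndarray | None = None
    covariance: np.ndarray | None = None
    margins: list[EmpiricalMargin] | None = None


def fit_distribution(
    X_refs, kind: str, log_transform: bool = True, shrinkage: float = 1e-6
) -> DistributionModel:
    """Estimate the feature-distribution model from the reference samples.

    ``shrinkage`` adds ``shrinkage * trace/m`` to the covariance diagonal;
    26 samples of 8 strongly correlated features are near-singular, and a
    usable Cholesky factorization is required for conditional sampling.
    Set it to 0 to fit without regularization (raises if singular).
    """
    if kind not in DISTRIBUTION_KINDS:
        raise InputError(f"unknown distribution kind {kind!r}; expected {DISTRIBUTION_KINDS}")
    if isinstance(X_refs, pd.DataFrame):
        feature_names = tuple(map(str, X_refs.columns))
        X = X_refs.to_numpy(dtype=float)
    else:
        X = np.asarray(X_refs, dtype=float)
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    if kind == "independent_reference":
        return DistributionModel(kind=kind, feature_names=feature_names)
    if log_transform:
        if np.any(X <= 0):
            raise InputError("intensities must be strictly positive for the log-space fit")
        X = np.log(X)
    m = X.shape[1]

    def _regularize(cov: np.ndarray) -> np.ndarray:
        cov = np.asarray(cov, dtype=float)
        if shrinkage > 0:
            cov = cov + shrinkage * (np.trace(cov) / m) * np.eye(m)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise PreconditionError(
                "singular covariance; increase the shrinkage regularization weight"
            ) from None
        return cov

    if kind == "multivariate_gaussian":
        return DistributionModel(
            kind=kind,
            feature_names=feature_names,
            location=X.mean(axis=0),
            covariance=_regularize(np.cov(X, rowvar=False, ddof=1)),
        )
    # gaussian_copula: margins on log scale, correlation on Gaussian scores
    margins = [EmpiricalMargin(X[:, i]) for i in range(m)]
    scores = np.column_stack(
        [norm.ppf(margins[i].pit(X[:, i])) for i in range(m)]
    )
    return DistributionModel(
        kind=kind,
        feature_names=feature_names,
        location=np.zeros(m),
        covariance=_regularize(np.cov(scores, rowvar=False, ddof=1)),
        margins=margins,
    )


def _conditional_gaussian(
    mu: np.ndarray, cov: np.ndarray, idx_in: list[int], idx_out: list[int], x_in: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the out coordinates given the in coordinates."""
    if not idx_in:
        return mu[idx_out], cov[np.ix_(idx_out, idx_out)]
    Sii = cov[np.ix_(idx_in, idx_in)]
    Soi = cov[np.ix_(idx_out, idx_in)]
    Soo = cov[np.ix_(idx_out, idx_out)]
    solve = np.linalg.solve(Sii, np.column_stack([x_in - mu[idx_in]]))
    mean = mu[idx_out] + (Soi @ solve).ravel()
    cov_out = Soo - Soi @ np.linalg.solve(Sii, Soi.T)
    return mean, cov_out


def _sample_mvn(
    mean: np.ndarray, cov: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    jitter = 1e-12 * max(float(np.trace(cov)) / max(len(mean), 1), 1.0)
    for _ in range(3):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(len(mean)))
            break
        except np.linalg.LinAlgError:
            jitter *= 1e3
    else:  # pragma: no cover - conditioned covariances are PSD by construction
        raise PreconditionError("conditional covariance not positive semidefinite")
    return mean + rng.standard_normal((n, len(mean))) @ L.T


# --------------------------------------------------------------------------
# explainers
# --------------------------------------------------------------------------
class _ShapExplainerBase(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing; subclasses build expectation tables."""

    method: str = "exact"  # overridden
    kind: str = "independent_reference"

    def __init__(self, k: int = 7, log_transform: bool = True):
        self.k = k
        self.log_transform = log_transform

    def fit(self, X, y):
        """Fit the underlying 7NN classifier (and any distribution model)
        on the labeled reference set."""
        self.classifier_ = SubsetKNNClassifier(
            k=self.k, log_transform=self.log_transform
        ).fit(X, y)
        self._fit_model(X)
        return self

    def _fit_model(self, X) -> None:  # overridden where a model is needed
        self.model_ = DistributionModel(
            kind=self.kind, feature_names=self.classifier_.feature_names_
        )

    # subclasses implement the expectation for one subset mask
    def _expectation(self, z: np.ndarray, mask: int, rng) -> float:
        raise NotImplementedError

    def _rng(self):
        return None

    def expectation_table(self, x, instance_id: str = "") -> SubsetValueTable:
        """E[f(S)] over the full subset lattice for one instance."""
        check_is_fitted(self, "classifier_")
        clf = self.classifier_
        z = clf._check_instances(x)[0]
        full_mask = 2 ** clf.n_features_in_ - 1
        rng = self._rng()
        values = np.empty(2 ** clf.n_features_in_)
        for mask in range(2 ** clf.n_features_in_):
            if mask == full_mask:
                # conditioning on everything: no sampling, f(M) exactly
                values[mask] = float(clf.predict_coords(z[None, :])[0])
            else:
                values[mask] = self._expectation(z, mask, rng)
        return SubsetValueTable(
            feature_names=clf.feature_names_, values=values, instance_id=instance_id
        )

    def conditional_expectation(self, x, subset) -> float:
        """E[f | features in ``subset`` fixed at the instance's values]."""
        check_is_fitted(self, "classifier_")
        clf = self.classifier_
        from .features import subset_mask

        mask = subset_mask(subset, clf.feature_names_)
        z = clf._check_instances(x)[0]
        if mask == 2 ** clf.n_features_in_ - 1:
            return float(clf.predict_coords(z[None, :])[0])
        return self._expectation(z, mask, self._rng())

    def explain_one(self, x, instance_id: str = "") -> Attribution:
        """Approximate Shapley values of one instance."""
        table = self.expectation_table(x, instance_id=instance_id)
        attr = shapley_values(table)
        return Attribution(
            instance_id=instance_id,
            method=self.method,
            feature_names=attr.feature_names,
            phi=attr.phi,
            null_value=attr.null_value,
            full_value=attr.full_value,
            meta=self._meta(),
        )

    def _meta(self) -> dict:
        return {}

    def transform(self, X) -> np.ndarray:
        """Attribution matrix, one row of phi per instance."""
        check_is_fitted(self, "classifier_")
        ids = list(X.index) if isinstance(X, pd.DataFrame) else range(len(np.atleast_2d(X)))
        X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.atleast_2d(
            np.asarray(X, dtype=float)
        )
        return np.vstack(
            [self.explain_one(row, instance_id=str(i)).phi for i, row in zip(ids, X_arr)]
        )


class ExactShapleyExplainer(_ShapExplainerBase):
    """Exact Shapley values via exhaustive subset retraining of the 7NN.

    Not an approximation: the value function is the restricted-subset
    classification with f(∅) = 0, evaluated for all 2**m subsets.
    """

    method = "exact"

    def expectation_table(self, x, instance_id: str = "") -> SubsetValueTable:
        check_is_fitted(self, "classifier_")
        return self.classifier_.subset_value_table(x, instance_id=instance_id)

    def _expectation(self, z, mask, rng):  # pragma: no cover - table path used
        return float(self.classifier_._vote_coords(z[None, :], mask)[0])


class KernelShapExplainer(_ShapExplainerBase):
    """Independent-feature (reference-replacement) kernel SHAP.

    E[f(S)] averages the full classification of the 26 hybrids obtained by
    keeping the instance's in-S values and substituting each reference
    sample's out-of-S values.  Deterministic; no distribution parameters.
    """

    method = "kernel_shap"
    kind = "independent_reference"

    def _expectation(self, z: np.ndarray, mask: int, rng) -> float:
        clf = self.classifier_
        hybrids = clf.coords_.copy()
        in_idx = [i for i in range(clf.n_features_in_) if mask >> i & 1]
        hybrids[:, in_idx] = z[in_idx]
        return float(clf.predict_coords(hybrids).mean())


class GaussianShapExplainer(_ShapExplainerBase):
    """Conditional SHAP under a multivariate Gaussian in log-feature space.

    Parameters
    ----------
    n_samples : Monte-Carlo draws per conditional expectation (1000).
    shrinkage : diagonal shrinkage weight for the fitted covariance.
    random_state : seed; required (refused when None) so every attribution
        is reproducible.
    """

    method = "gaussian_shap"
    kind = "multivariate_gaussian"

    def __init__(
        self,
        k: int = 7,
        log_transform: bool = True,
        n_samples: int = 1000,
        shrinkage: float = 1e-6,
        random_state: int | None = None,
    ):
        super().__init__(k=k, log_transform=log_transform)
        self.n_samples = n_samples
        self.shrinkage = shrinkage
        self.random_state = random_state

    def _fit_model(self, X) -> None:
        self.model_ = fit_distribution(
            X, self.kind, log_transform=self.log_transform, shrinkage=self.shrinkage
        )

    def _rng(self):
        if self.random_state is None:
            raise PreconditionError(
                "random_state must be set: Monte-Carlo attributions are only "
                "reported with an explicit seed"
            )
        return np.random.default_rng(self.random_state)

    def _meta(self) -> dict:
        return {"n_samples": self.n_samples, "seed": self.random_state}

    def _score_space(self, z: np.ndarray) -> np.ndarray:
        return z

    def _to_log_space(self, draws: np.ndarray, idx_out: list[int]) -> np.ndarray:
        return draws

    def _expectation(self, z: np.ndarray, mask: int, rng) -> float:
        clf = self.classifier_
        m = clf.n_features_in_
        idx_in = [i for i in range(m) if mask >> i & 1]
        idx_out = [i for i in range(m) if not mask >> i & 1]
        zs = self._score_space(z)
        mean, cov = _conditional_gaussian(
            self.model_.location, self.model_.covariance, idx_in, idx_out, zs[idx_in]
        )
        draws = _sample_mvn(mean, cov, self.n_samples, rng)
        samples = np.tile(z, (self.n_samples, 1))
        samples[:, idx_out] = self._to_log_space(draws, idx_out)
        return float(clf.predict_coords(samples).mean())


class CopulaShapExplainer(GaussianShapExplainer):
    """Conditional SHAP under a Gaussian copula with empirical margins.

    Log features are mapped through per-feature empirical CDFs (PIT) to
    Gaussian scores, the conditional distribution is evaluated in score
    space, and draws are mapped back through the inverse PIT before
    classification.
    """

    method = "copula_shap"
    kind = "gaussian_copula"

    def _score_space(self, z: np.ndarray) -> np.ndarray:
        margins = self.model_.margins
        return np.array(
            [float(norm.ppf(margins[i].pit(z[i]))) for i in range(len(z))]
        )

    def _to_log_space(self, draws: np.ndarray, idx_out: list[int]) -> np.ndarray:
        margins = self.model_.margins
        out = np.empty_like(draws)
        for col, i in enumerate(idx_out):
            out[:, col] = margins[i].inverse(norm.cdf(draws[:, col]))
        return out


# --------------------------------------------------------------------------
# module-level spec operations
# --------------------------------------------------------------------------
def kernel_shap(x, X_refs, y_refs, k: int = 7, log_transform: bool = True,
                instance_id: str = "") -> Attribution:
    """One-call kernel SHAP attribution for a single instance."""
    return (
        KernelShapExplainer(k=k, log_transform=log_transform)
        .fit(X_refs, y_refs)
        .explain_one(x, instance_id=instance_id)
    )


def approx_shapley(
    x,
    X_refs,
    y_refs,
    kind: str = "independent_reference",
    n_samples: int = 1000,
    random_state: int | None = None,
    k: int = 7,
    log_transform: bool = True,
    instance_id: str = "",
) -> Attribution:
    """Approximate Shapley values under the requested distribution kind."""
    if kind == "independent_reference":
        explainer = KernelShapExplainer(k=k, log_transform=log_transform)
    elif kind == "multivariate_gaussian":
        explainer = GaussianShapExplainer(
            k=k, log_transform=log_transform, n_samples=n_samples, random_state=random_state
        )
    elif kind == "gaussian_copula":
        explainer = CopulaShapExplainer(
            k=k, log_transform=log_transform, n_samples=n_samples, random_state=random_state
        )
    else:
        raise InputError(f"unknown distribution kind {kind!r}")
    return explainer.fit(X_refs, y_refs).explain_one(x, instance_id=instance_id)


def compare_to_exact(
    approx: list[Attribution],
    exact: list[Attribution],
    symmetry_tables: dict[str, SubsetValueTable] | None = None,
    tol: float = 1e-9,
) -> dict:
    """Mean-square difference between approximate and exact attributions.

    Returns overall MSD (mean over instances and features), the MSD
    restricted to uniform instances, and — when the exact subset-value
    tables are supplied — a per-instance listing of symmetry-axiom
    violations: feature pairs with identical subset behavior in the exact
    game but unequal approximate values.
    """
    by_id_exact = {a.instance_id: a for a in exact}
    if set(a.instance_id for a in approx) != set(by_id_exact):
        raise PreconditionError("approximate and exact attribution instance sets differ")
    sq, sq_uniform = [], []
    violations = []
    for ap in approx:
        ex = by_id_exact[ap.instance_id]
        if ap.feature_names != ex.feature_names:
            raise PreconditionError("feature sets differ between attributions")
        diff2 = (ap.phi - ex.phi) ** 2
        sq.append(diff2)
        if np.ptp(ex.phi) <= tol:  # uniform exact pattern
            sq_uniform.append(diff2)
        if symmetry_tables and ap.instance_id in symmetry_tables:
            table = symmetry_tables[ap.instance_id]
            for i_pos, i in enumerate(table.feature_names):
                for j_pos, j in enumerate(table.feature_names):
                    if j_pos <= i_pos:
                        continue
                    if _equal_subset_behavior(table, i_pos, j_pos) and abs(
                        ap.phi[i_pos] - ap.phi[j_pos]
                    ) > tol:
                        violations.append(
                            {
                                "instance_id": ap.instance_id,
                                "method": ap.method,
                                "feature_i": i,
                                "feature_j": j,
                                "delta": float(abs(ap.phi[i_pos] - ap.phi[j_pos])),
                            }
                        )
    result = {
        "method": approx[0].method if approx else "",
        "msd": float(np.mean(np.vstack(sq))) if sq else float("nan"),
        "msd_uniform": float(np.mean(np.vstack(sq_uniform))) if sq_uniform else float("nan"),
        "n_instances": len(approx),
        "n_uniform": len(sq_uniform),
    }
    if symmetry_tables is not None:
        result["symmetry_violations"] = violations
    return result


def _equal_subset_behavior(table: SubsetValueTable, i: int, j: int) -> bool:
    """True when f(S∪{i}) = f(S∪{j}) for every S excluding both — the
    hypothesis of the symmetry axiom."""
    both = (1 << i) | (1 << j)
    masks = np.arange(table.n_subsets)
    S = masks[(masks & both) == 0]
    return bool(np.all(table.values[S | (1 << i)] == table.values[S | (1 << j)]))
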