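"""Local surrogate (LIME-style) explanations of the 7NN classification.

The procedure:

1. Standardize each feature in log space: z_i = (log x_i - median_i) / s_i
   with s_i = IQR_i / 1.35 (the IQR of a Gaussian is 1.35 sigma), medians
   and IQRs taken from the pooled reference samples.
2. Generate class-conditional permutations: draw z ~ N(0, I) per feature
   (correlations deliberately ignored) and back-transform with the Good-
   or Poor-class medians/IQRs, n_per_class draws per class (5e5 each at
   full scale; desk-scale default 1e4).
3. Classify every permutation with the full 7NN and discard those whose
   classification does not match the class they were drawn from (~10% with
   overlapping classes).
4. Weight kept permutations by a Gaussian distance kernel
   w = exp(-d^2 / sigma^2), d the Euclidean distance to the explained
   instance in pooled-standardized space; sigma is the mean kept distance
   for the logistic surrogate and half of it for the SVM surrogate
   (optionally scaled by ``sigma_multiplier`` for boundary studies).
5. Fit a weighted surrogate on the standardized features — logistic
   regression (negligible ridge) or a linear-kernel SVM (unit cost) — and
   report its coefficient vector as the explanation, intercept as the
   null-set term.  Labels: Poor=0/Good=1 (logistic), -1/+1 (SVM); positive
   coefficients push toward Good.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .attribution import Attribution
from .errors import InputError, PreconditionError
from .knn import SubsetKNNClassifier

SIGMA_RULES = ("mean_distance", "half_mean_distance")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature log-space location/scale: median and IQR/1.35."""

    feature_names: tuple[str, ...]
    median: np.ndarray  # median of log intensity
    scale: np.ndarray  # IQR of log intensity / 1.35
    provenance: str = "pooled"  # pooled | Good | Poor

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.scale) <= 0):
            raise InputError("standardization scales must be strictly positive")


def estimate_standardization(
    X, provenance: str = "pooled", feature_names=None
) -> StandardizationParams:
    """Median and IQR/1.35 of log intensities over the given samples."""
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise InputError("intensities must be strictly positive")
    logX = np.log(X)
    q75, q25 = np.percentile(logX, [75, 25], axis=0)
    scale = (q75 - q25) / 1.35
    if np.any(scale <= 0):
        raise InputError(
            "degenerate IQR (zero spread) in at least one feature; cannot standardize"
        )
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    return StandardizationParams(
        feature_names=tuple(feature_names),
        median=np.median(logX, axis=0),
        scale=scale,
        provenance=provenance,
    )


def standardize(x, params: StandardizationParams) -> np.ndarray:
    """z_i = (log(x_i) - median_i) / scale_i."""
    x = np.asarray(
        x.reindex(list(params.feature_names)) if isinstance(x, pd.Series) else x,
        dtype=float,
    )
    if np.any(x <= 0):
        raise InputError("intensities must be strictly positive")
    return (np.log(x) - params.median) / params.scale


def destandardize(z, params: StandardizationParams) -> np.ndarray:
    """Inverse of :func:`standardize`: x = exp(scale * z + median)."""
    z = np.asarray(z, dtype=float)
    return np.exp(params.scale * z + params.median)


@dataclass
class PermutationSet:
    """Class-conditional permutations with discard flags.

    ``kept`` is True exactly when the full 7NN classification matches the
    class the permutation was drawn from.
    """

    feature_names: tuple[str, ...]
    X: np.ndarray  # raw intensities, (n, m)
    source_class: np.ndarray  # ±1 per row
    classification: np.ndarray  # ±1 per row (full 7NN)
    seed: int

    @property
    def kept(self) -> np.ndarray:
        return self.classification == self.source_class

    @property
    def discard_fraction(self) -> float:
        return 1.0 - float(self.kept.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["source_class"] = self.source_class
        df["classification"] = self.classification
        df["kept"] = self.kept
        return df


def generate_permutations(
    X_refs, y_refs, n_per_class: int, seed: int, k: int = 7
) -> PermutationSet:
    """Draw n_per_class standard-normal z vectors per class, back-transform
    with that class's median/IQR standardization, classify with the full
    7NN and flag discards.  Inter-feature correlations are ignored by
    design."""
    if n_per_class < 50:
        raise InputError("n_per_class is too small to fit a surrogate reliably")
    clf = SubsetKNNClassifier(k=k).fit(X_refs, y_refs)
    y_arr = np.asarray(y_refs)
    X_df = X_refs if isinstance(X_refs, pd.DataFrame) else pd.DataFrame(
        np.asarray(X_refs, dtype=float), columns=list(clf.feature_names_)
    )
    rng = np.random.default_rng(seed)
    blocks, sources = [], []
    for label, code in (("Good", 1), ("Poor", -1)):
        params = estimate_standardization(X_df[y_arr == label], provenance=label)
        z = rng.standard_normal((n_per_class, len(clf.feature_names_)))
        blocks.append(destandardize(z, params))
        sources.append(np.full(n_per_class, code, dtype=np.int8))
    X = np.vstack(blocks)
    source = np.concatenate(sources)
    classification = clf.predict(X).astype(np.int8)
    return PermutationSet(
        feature_names=clf.feature_names_,
        X=X,
        source_class=source,
        classification=classification,
        seed=seed,
    )


def weight_permutations(
    perms: PermutationSet,
    x,
    params: StandardizationParams,
    sigma_rule: str = "mean_distance",
    sigma_multiplier: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Gaussian kernel weights for the kept permutations.

    Distances are Euclidean in pooled-standardized space; sigma is the mean
    kept-permutation distance (``mean_distance``) or half of it
    (``half_mean_distance``), times ``sigma_multiplier``.  Returns
    (weights over kept permutations, sigma).
    """
    if sigma_rule not in SIGMA_RULES:
        raise InputError(f"unknown sigma rule {sigma_rule!r}; expected {SIGMA_RULES}")
    kept = perms.kept
    if not kept.any():
        raise PreconditionError("no kept permutations; cannot weight")
    Zk = np.array([standardize(row, params) for row in perms.X[kept]])
    zx = standardize(x, params)
    d = np.linalg.norm(Zk - zx, axis=1)
    sigma = float(d.mean()) * (0.5 if sigma_rule == "half_mean_distance" else 1.0)
    sigma *= sigma_multiplier
    if sigma <= 0:
        raise PreconditionError("degenerate kernel width sigma <= 0")
    return np.exp(-(d ** 2) / sigma ** 2), sigma


def fit_surrogate(
    perms: PermutationSet,
    weights: np.ndarray,
    params: StandardizationParams,
    model_kind: str = "logistic",
    instance_id: str = "",
) -> Attribution:
    """Weighted local surrogate on standardized features.

    The explanation is the coefficient vector (logistic-regression
    coefficients, or the normal vector of the linear SVM decision plane);
    the intercept is stored as the null-set term.
    """
    kept = perms.kept
    Zk = np.array([standardize(row, params) for row in perms.X[kept]])
    labels = perms.classification[kept]
    if len(np.unique(labels)) < 2:
        raise PreconditionError(
            "kept permutations contain a single class; instances with both "
            "classifications are required to train the local surrogate "
            "(the locality is too tight or the classes too separated)"
        )
    if model_kind == "logistic":
        # negligible ridge (C = 1e8) keeps the unpenalized fit conditioned
        model = LogisticRegression(C=1e8, max_iter=5000)
        model.fit(Zk, (labels == 1).astype(int), sample_weight=weights)
        method = "lime_logistic"
    elif model_kind == "linear_svm":
        model = LinearSVC(C=1.0, loss="hinge", max_iter=20000, tol=1e-5)
        model.fit(Zk, labels, sample_weight=weights)
        method = "lime_svm"
    else:
        raise InputError(f"unknown surrogate kind {model_kind!r}")
    return Attribution(
        instance_id=instance_id,
        method=method,
        feature_names=perms.feature_names,
        phi=model.coef_.ravel(),
        null_value=float(np.ravel(model.intercept_)[0]),
        full_value=None,
        meta={"seed": perms.seed, "n_kept": int(kept.sum())},
    )


class LimeExplainer(TransformerMixin, BaseEstimator):
    """Local-surrogate explainer composing the steps above.

    Parameters
    ----------
    surrogate : ``"logistic"`` or ``"linear_svm"``.
    n_per_class : permutations drawn per class (1e4 default; 5e5 at full
        scale).
    sigma_rule : kernel-width rule; ``None`` selects the surrogate's
        canonical rule (mean distance for logistic, half for SVM).
    sigma_multiplier : extra width factor for boundary-region studies.
    random_state : seed for permutation generation; required.
    """

    def __init__(
        self,
        surrogate: str = "logistic",
        n_per_class: int = 10_000,
        sigma_rule: str | None = None,
        sigma_multiplier: float = 1.0,
        k: int = 7,
        random_state: int | None = None,
    ):
        self.surrogate = surrogate
        self.n_per_class = n_per_class
        self.sigma_rule = sigma_rule
        self.sigma_multiplier = sigma_multiplier
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        """Fit the 7NN on the reference set, estimate pooled
        standardization, and generate the class-conditional permutations."""
        if self.random_state is None:
            raise PreconditionError("random_state must be set for permutation generation")
        if self.surrogate not in ("logistic", "linear_svm"):
            raise InputError(f"unknown surrogate kind {self.surrogate!r}")
        self.params_ = estimate_standardization(
            X if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        )
        self.permutations_ = generate_permutations(
            X, y, n_per_class=self.n_per_class, seed=self.random_state, k=self.k
        )
        return self

    def _rule(self) -> str:
        if self.sigma_rule is not None:
            return self.sigma_rule
        return "mean_distance" if self.surrogate == "logistic" else "half_mean_distance"

    def explain_one(self, x, instance_id: str = "") -> Attribution:
        check_is_fitted(self, "permutations_")
        weights, sigma = weight_permutations(
            self.permutations_,
            x,
            self.params_,
            sigma_rule=self._rule(),
            sigma_multiplier=self.sigma_multiplier,
        )
        attr = fit_surrogate(
            self.permutations_,
            weights,
            self.params_,
            model_kind=self.surrogate,
            instance_id=instance_id,
        )
        attr.meta["sigma"] = sigma
        return attr

    def transform(self, X) -> np.ndarray:
        """Surrogate coefficient matrix, one row per instance."""
        check_is_fitted(self, "permutations_")
        ids = list(X.index) if isinstance(X, pd.DataFrame) else range(len(np.atleast_2d(X)))
        X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.atleast_2d(
            np.asarray(X, dtype=float)
        )
        return np.vstack(
            [self.explain_one(row, instance_id=str(i)).phi for i, row in zip(ids, X_arr)]
        )
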