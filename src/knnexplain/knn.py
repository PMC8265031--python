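"""The diagnostic k-nearest-neighbor classifier and its subset restrictions.

The test classifies one instance (a vector of eight positive mass-spectral
feature intensities) by majority vote among its k = 7 nearest neighbors in a
26-sample reference set (13 labelled Good, 13 Poor).  Restricting the
distance computation to an arbitrary feature subset defines the value
function f(S) that every explanation method in this package consumes:
f(S) = +1 (Good majority), -1 (Poor majority), and f(∅) = 0 by convention
(the classifier with no features is uninformative).

Distances are Euclidean, by default on log-transformed intensities (the same
log scale used for standardization elsewhere in the pipeline); a raw-scale
switch is provided.  Distance ties at the k-th neighbor are broken by lowest
reference-sample index (a stable sort), so identical inputs always yield
identical outputs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InputError, PreconditionError
from .features import (
    CANONICAL_FEATURES,
    LABEL_DECODING,
    LABEL_ENCODING,
    subset_mask,
)
from .tables import SubsetValueTable


def _encode_labels(y) -> np.ndarray:
    """Map labels to the canonical encoding Poor = -1, Good = +1."""
    y = np.asarray(y)
    out = np.empty(len(y), dtype=np.int8)
    for i, label in enumerate(y):
        if isinstance(label, str):
            if label not in LABEL_ENCODING:
                raise InputError(f"unknown class label {label!r}; expected Good/Poor")
            out[i] = LABEL_ENCODING[label]
        else:
            v = int(label)
            if v not in (-1, 1):
                raise InputError(f"numeric labels must be -1 (Poor) or +1 (Good), got {label!r}")
            out[i] = v
    return out


class SubsetKNNClassifier(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbor classifier restrictable to feature subsets.

    Parameters
    ----------
    k : int, default 7
        Neighbor count; must be odd (an odd k makes majority votes
        tie-free) and at most the reference-set size.
    log_transform : bool, default True
        Compute Euclidean distances on log intensities.  Requires strictly
        positive inputs.

    Attributes
    ----------
    coords_ : ndarray of shape (n_refs, n_features)
        Reference coordinates in distance space (log or raw).
    y_ : ndarray of shape (n_refs,)
        Reference labels encoded ±1.
    feature_names_ : tuple of str
        Feature names, defining bit order of subset masks.
    classes_ : ndarray
        ``[-1, 1]``.
    """

    def __init__(self, k: int = 7, log_transform: bool = True):
        self.k = k
        self.log_transform = log_transform

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        """Store the reference set.

        ``X`` is (n_refs, n_features) positive intensities (DataFrame column
        names are used as feature names); ``y`` holds labels as
        ``"Good"``/``"Poor"`` strings or ±1 integers.
        """
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = tuple(map(str, X.columns))
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("reference X must be 2-dimensional")
        n, m = X.shape
        if feature_names is None:
            feature_names = CANONICAL_FEATURES if m == len(CANONICAL_FEATURES) else tuple(
                f"f{i}" for i in range(m)
            )
        if len(feature_names) != m:
            raise InputError("feature_names length does not match X")
        y_enc = _encode_labels(y)
        if len(y_enc) != n:
            raise InputError("X and y have different lengths")
        if self.k % 2 == 0 or self.k < 1:
            raise InputError(f"k must be odd and positive, got {self.k}")
        if self.k > n:
            raise InputError(f"k = {self.k} exceeds reference-set size {n}")
        self.coords_ = self._to_coords(X)
        self.y_ = y_enc
        self.feature_names_ = tuple(map(str, feature_names))
        self.n_features_in_ = m
        self.classes_ = np.array([-1, 1])
        return self

    def _to_coords(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.log_transform:
            if np.any(X <= 0) or not np.all(np.isfinite(X)):
                raise InputError(
                    "all intensities must be strictly positive and finite "
                    "when log-distance is configured"
                )
            return np.log(X)
        return X

    def _check_instances(self, X) -> np.ndarray:
        if isinstance(X, (pd.DataFrame, pd.Series)):
            if isinstance(X, pd.Series):
                X = X.to_frame().T
            X = X.reindex(columns=list(self.feature_names_)).to_numpy(dtype=float)
            if np.any(np.isnan(X)):
                raise InputError("instance table is missing canonical feature columns")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._to_coords(X)

    # ----------------------------------------------------- subset votes
    def _vote_coords(self, Z: np.ndarray, mask: int) -> np.ndarray:
        """Majority 7NN vote for rows of Z (already in distance space),
        using only the coordinates in ``mask``.  Returns ±1 per row, or 0
        for the empty mask."""
        check_is_fitted(self, "coords_")
        if mask == 0:
            return np.zeros(Z.shape[0], dtype=np.int8)
        idx = [i for i in range(self.n_features_in_) if mask >> i & 1]
        d2 = ((Z[:, None, idx] - self.coords_[None, :, idx]) ** 2).sum(axis=-1)
        # stable argsort -> ties at the k-th neighbor resolved by lowest
        # reference index
        nearest = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        votes = self.y_[nearest].sum(axis=1)
        return np.sign(votes).astype(np.int8)  # k odd => never 0

    def classify_subset(self, x, subset: Iterable[str]) -> int:
        """Classification of one instance by the classifier restricted to
        ``subset`` (an iterable of feature names): +1 Good, -1 Poor, 0 for
        the empty subset."""
        check_is_fitted(self, "coords_")
        mask = subset_mask(subset, self.feature_names_)
        Z = self._check_instances(x)
        if Z.shape[0] != 1:
            raise InputError("classify_subset expects a single instance")
        return int(self._vote_coords(Z, mask)[0])

    def subset_value_table(self, x, instance_id: str = "") -> SubsetValueTable:
        """Exact value function of one instance over all 2**m subsets."""
        check_is_fitted(self, "coords_")
        Z = self._check_instances(x)
        if Z.shape[0] != 1:
            raise InputError("subset_value_table expects a single instance")
        n_subsets = 2 ** self.n_features_in_
        values = np.empty(n_subsets)
        for mask in range(n_subsets):
            values[mask] = self._vote_coords(Z, mask)[0]
        return SubsetValueTable(
            feature_names=self.feature_names_, values=values, instance_id=instance_id
        )

    # ------------------------------------------------------------- predict
    def predict(self, X) -> np.ndarray:
        """Full-feature classification, ±1 per row."""
        check_is_fitted(self, "coords_")
        Z = self._check_instances(X)
        return self._vote_coords(Z, 2 ** self.n_features_in_ - 1).astype(int)

    def predict_coords(self, Z: np.ndarray) -> np.ndarray:
        """Full-feature classification of rows already in distance space
        (log intensities when ``log_transform``).  Used by samplers that
        work natively in log space."""
        check_is_fitted(self, "coords_")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self._vote_coords(Z, 2 ** self.n_features_in_ - 1).astype(int)

    def classify_replicates(self, X) -> str:
        """Reported test label from technical replicates: ``Good`` if every
        replicate classifies +1, ``Poor`` if every one is -1, otherwise
        ``Indeterminate``."""
        X = np.atleast_2d(np.asarray(X, dtype=float)) if not isinstance(
            X, pd.DataFrame
        ) else X
        if len(X) == 0:
            raise InputError("at least one replicate is required")
        preds = self.predict(X)
        if np.all(preds == 1):
            return LABEL_DECODING[1]
        if np.all(preds == -1):
            return LABEL_DECODING[-1]
        return LABEL_DECODING[0]
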