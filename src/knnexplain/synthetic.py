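"""Synthetic cohorts emulating the statistical structure of the test data.

The real reference set and patient cohort are not publicly available, so
this module generates stand-ins with the documented structure: eight
strictly positive, strongly correlated, roughly log-normal feature
intensities; a balanced 13 Good / 13 Poor reference set whose classes
occupy separated regions of feature space; instances in the class bulk
("uniform"), intermediate, or straddling the decision surface ("boundary");
and technical-replicate noise.

Features are multivariate log-normal: Gaussian in log space with an
equicorrelated covariance (correlation defaults to 0.7, inside the strong
inter-feature correlation range seen for serum-amyloid-A isoform panels).
Class centers sit ``separation`` apart (Euclidean, log space) along the
all-features diagonal, so every feature is individually informative.
Technical replicates add i.i.d. Gaussian noise in log space.

Every output is fully determined by (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError, PreconditionError
from .features import CANONICAL_FEATURES
from .knn import SubsetKNNClassifier


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for reference sets and cohorts.

    Parameters
    ----------
    n_good, n_poor : reference-set class sizes (13 / 13).
    feature_names : names of the generated features.
    base_log_mean : grand mean of log intensity (arbitrary units; exp(5)
        ~ 150 intensity counts).
    log_sd : per-feature standard deviation of log intensity (0.5, i.e.
        ~1.6-fold multiplicative scatter).
    correlation : common inter-feature correlation in log space (0.7).
    separation : Euclidean distance between class centers in log space.
        The class axis coincides with the dominant (shared-amplitude)
        variance direction, whose within-class SD is
        log_sd * sqrt(1 + (m-1) rho) ~ 1.2 at the defaults; the default
        6.0 puts each class center ~2.5 of those SDs from the midpoint,
        giving well-separated classes with occasional near-boundary
        samples.
    replicate_noise_sd : log-space technical noise per replicate (0.05,
        i.e. ~5% multiplicative noise).
    tail_df : when set (> 2), log-space innovations are Student-t with
        this many degrees of freedom scaled to unit variance — heavier
        tails than Gaussian, for stress-testing margin-sensitive methods.
    seed : base seed; all generation derives from it.
    """

    n_good: int = 13
    n_poor: int = 13
    feature_names: tuple[str, ...] = CANONICAL_FEATURES
    base_log_mean: float = 5.0
    log_sd: float = 0.5
    correlation: float = 0.7
    separation: float = 6.0
    replicate_noise_sd: float = 0.05
    tail_df: float | None = None
    seed: int = 0

    @property
    def m(self) -> int:
        return len(self.feature_names)

    def covariance(self) -> np.ndarray:
        """Equicorrelated log-space covariance sd^2 [(1-rho) I + rho J]."""
        m = self.m
        rho = self.correlation
        if not -1.0 / (m - 1) < rho < 1.0:
            raise InputError(f"correlation {rho} is not positive definite for m={m}")
        return self.log_sd ** 2 * ((1 - rho) * np.eye(m) + rho * np.ones((m, m)))

    def class_center(self, label: str) -> np.ndarray:
        """Class center in log space; Good and Poor sit ±separation/2 along
        the all-features diagonal."""
        if self.separation < 0:
            raise InputError("separation must be non-negative")
        direction = np.ones(self.m) / np.sqrt(self.m)
        sign = {"Good": +1.0, "Poor": -1.0}.get(label)
        if sign is None:
            raise InputError(f"unknown class label {label!r}")
        return self.base_log_mean + sign * 0.5 * self.separation * direction

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def _draw_class(spec: CohortSpec, label: str, n: int, rng: np.random.Generator) -> np.ndarray:
    center = spec.class_center(label)
    L = np.linalg.cholesky(spec.covariance() + 1e-12 * np.eye(spec.m))
    if spec.tail_df is not None:
        if spec.tail_df <= 2:
            raise InputError("tail_df must exceed 2 so the variance is finite")
        Z = rng.standard_t(spec.tail_df, size=(n, spec.m))
        Z /= np.sqrt(spec.tail_df / (spec.tail_df - 2.0))  # unit variance
    else:
        Z = rng.standard_normal((n, spec.m))
    return np.exp(center + Z @ L.T)


def make_reference_set(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Labeled reference set: (X, y) with ``spec.n_good + spec.n_poor``
    rows, feature columns named per spec, sample ids ``ref_*`` and labels
    ``Good``/``Poor``."""
    if spec.n_good < 1 or spec.n_poor < 1:
        raise InputError("both classes need at least one reference sample")
    rng = np.random.default_rng(spec.seed)
    Xg = _draw_class(spec, "Good", spec.n_good, rng)
    Xp = _draw_class(spec, "Poor", spec.n_poor, rng)
    X = np.vstack([Xg, Xp])
    labels = ["Good"] * spec.n_good + ["Poor"] * spec.n_poor
    ids = [f"ref_{i:02d}" for i in range(len(labels))]
    X_df = pd.DataFrame(X, columns=list(spec.feature_names), index=ids)
    y = pd.Series(labels, index=ids, name="label")
    return X_df, y


def reference_self_consistency(
    X: pd.DataFrame, y: pd.Series, k: int = 7, log_transform: bool = True
) -> pd.Series:
    """Boolean per reference sample: does the full classifier reproduce its
    own label?  With separation 0 the classes are indistinguishable and
    this reports failures rather than raising."""
    clf = SubsetKNNClassifier(k=k, log_transform=log_transform).fit(X, y)
    encoded = np.where(np.asarray(y) == "Good", 1, -1)
    return pd.Series(clf.predict(X) == encoded, index=X.index, name="self_consistent")


def make_uniform_instance(
    X_refs: pd.DataFrame,
    y_refs: pd.Series,
    label: str,
    k: int = 7,
    log_transform: bool = True,
    max_retries: int = 8,
) -> pd.Series:
    """Construct an instance whose every non-empty feature subset classifies
    to ``label`` (verified exhaustively over all 2**m subsets).

    Starts at the target-class log-space centroid and steps deeper into the
    class (away from the other class centroid) until verification passes.
    """
    target = {"Good": 1, "Poor": -1}.get(label)
    if target is None:
        raise InputError(f"unknown class label {label!r}")
    clf = SubsetKNNClassifier(k=k, log_transform=log_transform).fit(X_refs, y_refs)
    logX = np.log(X_refs.to_numpy(dtype=float)) if log_transform else X_refs.to_numpy(float)
    own = logX[np.asarray(y_refs) == label].mean(axis=0)
    other = logX[np.asarray(y_refs) != label].mean(axis=0)
    step = own - other
    for trial in range(max_retries):
        candidate = own + (0.0 if trial == 0 else 0.5 * 2 ** (trial - 1)) * step
        x = np.exp(candidate) if log_transform else candidate
        table = clf.subset_value_table(x, instance_id=f"uniform_{label}")
        if np.all(table.values[1:] == target) and table.values[0] == 0:
            return pd.Series(x, index=list(X_refs.columns), name=f"uniform_{label}")
    raise PreconditionError(
        f"could not construct a uniform {label} instance in {max_retries} retries; "
        "increase class separation"
    )


def make_boundary_instance(
    X_refs: pd.DataFrame,
    y_refs: pd.Series,
    x_good=None,
    x_poor=None,
    k: int = 7,
    log_transform: bool = True,
    tol: float = 1e-10,
) -> pd.Series:
    """Bisect (in log space) between a Good-classified and a Poor-classified
    point until the bracketing interval is below ``tol``; return the
    midpoint.  The result sits on the full-classifier decision surface, so
    its exact Shapley values are typically non-uniform."""
    clf = SubsetKNNClassifier(k=k, log_transform=log_transform).fit(X_refs, y_refs)
    cols = list(X_refs.columns)
    if x_good is None:
        x_good = np.exp(np.log(X_refs[np.asarray(y_refs) == "Good"].to_numpy(float)).mean(0))
    if x_poor is None:
        x_poor = np.exp(np.log(X_refs[np.asarray(y_refs) == "Poor"].to_numpy(float)).mean(0))
    a = np.log(np.asarray(x_good, dtype=float))
    b = np.log(np.asarray(x_poor, dtype=float))
    fa = int(clf.predict(np.exp(a))[0])
    fb = int(clf.predict(np.exp(b))[0])
    if fa == fb:
        raise InputError("bisection endpoints classify identically; need one Good and one Poor")
    while np.linalg.norm(a - b) > tol:
        mid = 0.5 * (a + b)
        fm = int(clf.predict(np.exp(mid))[0])
        if fm == fa:
            a = mid
        else:
            b = mid
    return pd.Series(np.exp(0.5 * (a + b)), index=cols, name="boundary")


def make_cohort(
    spec: CohortSpec,
    n_good: int | None = None,
    n_poor: int | None = None,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort of instances (optionally with technical replicates).

    Returns ``(instances, truth)``.  ``instances`` has one row per
    (sample, replicate) with columns ``sample_id``, ``replicate`` and the
    features; ``truth`` holds the generating class per sample, kept
    separate from the feature table so labels cannot leak into pipelines.
    Replicate noise is i.i.d. Gaussian in log space with
    ``spec.replicate_noise_sd``.
    """
    n_good = spec.n_good if n_good is None else n_good
    n_poor = spec.n_poor if n_poor is None else n_poor
    if n_replicates < 1:
        raise InputError("n_replicates must be at least 1")
    # separate stream from make_reference_set so refs and cohort are independent
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 12289]))
    rows = []
    truth = []
    counter = 0
    for label, n in (("Good", n_good), ("Poor", n_poor)):
        base = np.log(_draw_class(spec, label, n, rng))
        for s in range(n):
            sample_id = f"sample_{counter:04d}"
            truth.append({"sample_id": sample_id, "true_class": label})
            for r in range(n_replicates):
                noise = (
                    rng.standard_normal(spec.m) * spec.replicate_noise_sd
                    if spec.replicate_noise_sd > 0
                    else np.zeros(spec.m)
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "replicate": r + 1,
                        **dict(zip(spec.feature_names, np.exp(base[s] + noise))),
                    }
                )
            counter += 1
    return pd.DataFrame(rows), pd.DataFrame(truth)
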