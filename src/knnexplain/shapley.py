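"""Exact Shapley values from a complete subset-value table.

For a value function f over subsets of the feature set M, the Shapley value
of feature j is

    psi_j = sum_{S ⊆ M\\{j}}  |S|! (|M|-|S|-1)! / |M|!  [f(S ∪ {j}) - f(S)]

Weights are assembled from exact integer factorials and divided once, so on
±1 classification games the sums are exact to machine rounding.  The
permutation-average oracle (psi_j = mean over all |M|! feature orderings of
j's marginal contribution) is provided as an independent cross-check; it is
mathematically identical to the weighted subset sum.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np

from .attribution import Attribution
from .errors import InputError, PreconditionError
from .features import DEFAULT_PROBE_PAIR
from .tables import SubsetValueTable, popcounts


def shapley_values(table: SubsetValueTable) -> Attribution:
    """Exact Shapley values of every feature via the weighted subset sum."""
    m = table.m
    v = table.values
    pc = popcounts(table.n_subsets)
    # integer numerators |S|!(m-|S|-1)!; single division by m! at the end
    num = np.array([factorial(s) * factorial(m - s - 1) for s in range(m)], dtype=float)
    denom = float(factorial(m))
    phi = np.empty(m)
    all_masks = np.arange(table.n_subsets)
    for j in range(m):
        bit = 1 << j
        without = all_masks[(all_masks & bit) == 0]
        diffs = v[without | bit] - v[without]
        phi[j] = float(np.sum(num[pc[without]] * diffs)) / denom
    return Attribution(
        instance_id=table.instance_id,
        method="exact",
        feature_names=table.feature_names,
        phi=phi,
        null_value=table.null_value,
        full_value=table.full_value,
    )


def shapley_permutation_oracle(table: SubsetValueTable) -> Attribution:
    """Shapley values by brute-force average over all |M|! orderings.

    Independent of :func:`shapley_values`; factorial cost, refused above
    |M| = 10.
    """
    m = table.m
    if m > 10:
        raise PreconditionError(
            f"permutation oracle enumerates |M|! orderings; |M| = {m} > 10 refused"
        )
    v = table.values
    totals = np.zeros(m)
    count = 0
    for order in permutations(range(m)):
        mask = 0
        for j in order:
            new = mask | (1 << j)
            totals[j] += v[new] - v[mask]
            mask = new
        count += 1
    return Attribution(
        instance_id=table.instance_id,
        method="exact",
        feature_names=table.feature_names,
        phi=totals / count,
        null_value=table.null_value,
        full_value=table.full_value,
    )


def classify_sv_pattern(
    attr: Attribution,
    probe_pair: tuple[str, str] = DEFAULT_PROBE_PAIR,
    tol: float = 1e-9,
) -> str:
    """Tag an exact attribution as ``uniform`` (all Shapley values equal),
    ``boundary`` (the two probe features' values differ) or ``other``.

    Uniform instances sit in the bulk of a classification region: every
    non-empty subset classifies identically, so all values share magnitude
    1/|M|.  Boundary instances sit near the decision surface, where the two
    dominant probe features can pull in opposite directions.
    """
    if attr.method != "exact":
        raise PreconditionError(
            f"pattern taxonomy is defined for exact Shapley values, got {attr.method!r}"
        )
    a, b = (attr[p] for p in probe_pair)  # raises InputError if absent
    if np.ptp(attr.phi) <= tol:
        return "uniform"
    if abs(a - b) > tol:
        return "boundary"
    return "other"


def replicate_sv_reproducibility(a: Attribution, b: Attribution) -> np.ndarray:
    """Per-feature perpendicular distance |psi_a - psi_b| / sqrt(2) from the
    point (psi_a, psi_b) to the y = x line — the replicate-agreement metric
    for Shapley values of two technical replicates of one sample."""
    if a.feature_names != b.feature_names:
        raise InputError("attributions have mismatched feature sets")
    return np.abs(a.phi - b.phi) / np.sqrt(2.0)


def perpendicular_distance_histogram(
    distances: np.ndarray, bin_edges: np.ndarray
) -> np.ndarray:
    """Histogram of perpendicular distances normalized by the total number
    of (feature, sample) points, so the bin masses sum to 1 when the edges
    cover the data."""
    distances = np.asarray(distances, dtype=float).ravel()
    if distances.size == 0:
        raise InputError("no distances to histogram")
    counts, _ = np.histogram(distances, bins=np.asarray(bin_edges, dtype=float))
    return counts / distances.size
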