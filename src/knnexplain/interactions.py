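"""Pairwise Shapley-style interaction metrics.

Four metrics over an exact subset-value table, all functions of the second
difference  D_ij f(S) = f(S∪{i,j}) - f(S∪{i}) - f(S∪{j}) + f(S):

* SII  — Shapley interaction index, coalition-weighted sum of D_ij over all
  S ⊆ M\\{i,j}; diagonal main effect SII_ii = psi_i - sum_{j≠i} SII_ij.
* STII — Shapley-Taylor interaction index (order 2), same sum with twice
  the ordinary Shapley weight; diagonal main effect f({i}) - f(∅).
* HD   — two-feature Harsanyi dividend f({i,j}) - f({i}) - f({j}) - 2 f(∅),
  the pure pair synergy ignoring larger coalitions; no diagonal.
* SPS  — Shapley partial sum: the part of feature j's Shapley value
  contributed by coalitions that already contain feature i,

      SPS_ij = sum_{S ⊆ M\\{i,j}} (|M|-|S|-2)! (|S|+1)! / |M|!
               [f(S∪{i,j}) - f(S∪{i})].

  Unlike the first three, SPS is asymmetric: adding a weakly informative
  feature on top of a strongly informative one is not the same as the
  reverse.  The complementary sum (over coalitions without i) plus SPS_ij
  recomposes psi_j exactly.

The SII here follows the pair-of-indices normalization; the subset-of-two
convention is twice this value and is available via ``pair_convention``.
"""

from __future__ import annotations

from math import factorial

import numpy as np
import pandas as pd

from .errors import InputError
from .features import feature_indices
from .shapley import shapley_values
from .tables import SubsetValueTable, popcounts

METRICS = ("SII", "STII", "HD", "SPS")


def _pair_setup(table: SubsetValueTable, i: str, j: str):
    bi, bj = feature_indices([i, j], table.feature_names)
    if bi == bj:
        raise InputError(f"feature pair must be distinct, got ({i!r}, {j!r})")
    m = table.m
    if m < 2:
        raise InputError("pairwise metrics need at least two features")
    all_masks = np.arange(table.n_subsets)
    both = (1 << bi) | (1 << bj)
    S = all_masks[(all_masks & both) == 0]
    return bi, bj, m, S


def _second_difference(table: SubsetValueTable, bi: int, bj: int, S: np.ndarray) -> np.ndarray:
    v = table.values
    return v[S | (1 << bi) | (1 << bj)] - v[S | (1 << bi)] - v[S | (1 << bj)] + v[S]


def sii_pair(table: SubsetValueTable, i: str, j: str, pair_convention: bool = True) -> float:
    """Shapley interaction index of the distinct pair (i, j).

    ``pair_convention=False`` doubles the value, giving the subset-of-two
    normalization used by some libraries.
    """
    bi, bj, m, S = _pair_setup(table, i, j)
    pc = popcounts(table.n_subsets)
    num = np.array(
        [factorial(s) * factorial(m - s - 2) for s in range(m - 1)], dtype=float
    )
    denom = 2.0 * factorial(m - 1)
    val = float(np.sum(num[pc[S]] * _second_difference(table, bi, bj, S))) / denom
    return val if pair_convention else 2.0 * val


def sii_main(table: SubsetValueTable, i: str, pair_convention: bool = True) -> float:
    """SII main effect: psi_i minus the sum of i's off-diagonal SIIs."""
    phi_i = shapley_values(table)[i]
    off = sum(
        sii_pair(table, i, j, pair_convention=pair_convention)
        for j in table.feature_names
        if j != str(i)
    )
    return phi_i - off


def stii_pair(table: SubsetValueTable, i: str, j: str) -> float:
    """Shapley-Taylor interaction index (order 2) of the distinct pair."""
    bi, bj, m, S = _pair_setup(table, i, j)
    pc = popcounts(table.n_subsets)
    num = np.array(
        [2 * factorial(s) * factorial(m - s - 1) for s in range(m - 1)], dtype=float
    )
    denom = float(factorial(m))
    return float(np.sum(num[pc[S]] * _second_difference(table, bi, bj, S))) / denom


def stii_main(table: SubsetValueTable, i: str) -> float:
    """STII main effect: f({i}) - f(∅), the single-feature classification
    relative to the uninformative null."""
    (bi,) = feature_indices([i], table.feature_names)
    return float(table.values[1 << bi] - table.values[0])


def harsanyi_pair(table: SubsetValueTable, i: str, j: str) -> float:
    """Two-feature Harsanyi dividend f({i,j}) - f({i}) - f({j}) - 2 f(∅)."""
    bi, bj, _, _ = _pair_setup(table, i, j)
    v = table.values
    return float(v[(1 << bi) | (1 << bj)] - v[1 << bi] - v[1 << bj] - 2.0 * v[0])


def sps(table: SubsetValueTable, i: str, j: str) -> float:
    """Shapley partial sum SPS_ij: feature j's contribution to coalitions
    already containing feature i.  Asymmetric in (i, j)."""
    bi, bj, m, S = _pair_setup(table, i, j)
    pc = popcounts(table.n_subsets)
    num = np.array(
        [factorial(m - s - 2) * factorial(s + 1) for s in range(m - 1)], dtype=float
    )
    denom = float(factorial(m))
    v = table.values
    diffs = v[S | (1 << bi) | (1 << bj)] - v[S | (1 << bi)]
    return float(np.sum(num[pc[S]] * diffs)) / denom


def shapley_split(table: SubsetValueTable, i: str, j: str) -> tuple[float, float]:
    """Split psi_j into (coalitions-with-i, coalitions-without-i) terms.

    The first term equals :func:`sps`; the two terms sum to psi_j exactly.
    """
    bi, bj, m, S = _pair_setup(table, i, j)
    with_i = sps(table, i, j)
    pc = popcounts(table.n_subsets)
    num = np.array(
        [factorial(s) * factorial(m - s - 1) for s in range(m - 1)], dtype=float
    )
    denom = float(factorial(m))
    v = table.values
    without_i = float(np.sum(num[pc[S]] * (v[S | (1 << bj)] - v[S]))) / denom
    return with_i, without_i


def interaction_matrix(
    table: SubsetValueTable, metric: str, pair_convention: bool = True
) -> pd.DataFrame:
    """|M| x |M| DataFrame of one pairwise metric.

    The diagonal holds main effects for SII and STII and NaN ("not
    defined", distinct from a computed 0) for HD and SPS.  SPS rows are the
    conditioning feature i, columns the contributing feature j.
    """
    metric = metric.upper()
    if metric not in METRICS:
        raise InputError(f"unknown metric {metric!r}; expected one of {METRICS}")
    names = table.feature_names
    out = pd.DataFrame(np.nan, index=list(names), columns=list(names))
    for i in names:
        for j in names:
            if i == j:
                if metric == "SII":
                    out.loc[i, j] = sii_main(table, i, pair_convention=pair_convention)
                elif metric == "STII":
                    out.loc[i, j] = stii_main(table, i)
            elif metric == "SII":
                out.loc[i, j] = sii_pair(table, i, j, pair_convention=pair_convention)
            elif metric == "STII":
                out.loc[i, j] = stii_pair(table, i, j)
            elif metric == "HD":
                out.loc[i, j] = harsanyi_pair(table, i, j)
            else:
                out.loc[i, j] = sps(table, i, j)
    return out


def interaction_long_frame(
    table: SubsetValueTable, metrics: tuple[str, ...] = METRICS
) -> pd.DataFrame:
    """Long export `instance_id,metric,feature_i,feature_j,value` for the
    requested metrics; undefined diagonals are omitted."""
    rows = []
    for metric in metrics:
        mat = interaction_matrix(table, metric)
        for i in mat.index:
            for j in mat.columns:
                value = mat.loc[i, j]
                if np.isnan(value):
                    continue
                rows.append(
                    {
                        "instance_id": table.instance_id,
                        "metric": metric.upper(),
                        "feature_i": i,
                        "feature_j": j,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)
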