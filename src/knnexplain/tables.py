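"""Subset-value tables: the value function f(S) over the full coalition lattice.

A :class:`SubsetValueTable` stores one real value per feature subset of one
instance, indexed by bitmask (bit ``i`` set iff feature ``feature_names[i]``
is in the subset).  For the exact game the values are the restricted-subset
7NN classifications (+1 Good / -1 Poor, 0 for the empty set); for the SHAP
approximations they are conditional expectations in [-1, +1].

The canonical enumeration order used for export and error reporting is by
subset size, then lexicographically by the member tuple in canonical feature
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PreconditionError
from .features import mask_members, subset_mask


def popcounts(n_subsets: int) -> np.ndarray:
    """Vector of set-bit counts for 0..n_subsets-1."""
    masks = np.arange(n_subsets, dtype=np.uint32)
    counts = np.zeros(n_subsets, dtype=np.int64)
    while masks.any():
        counts += masks & 1
        masks >>= 1
    return counts


def canonical_subset_order(m: int) -> list[int]:
    """All 2**m bitmasks sorted by subset size then lexicographically by
    member index tuple."""
    def key(mask: int) -> tuple:
        members = tuple(i for i in range(m) if mask >> i & 1)
        return (len(members), members)

    return sorted(range(2 ** m), key=key)


@dataclass(frozen=True)
class SubsetValueTable:
    """Complete value function of one instance over all 2**m feature subsets."""

    feature_names: tuple[str, ...]
    values: np.ndarray  # shape (2**m,), float; index = bitmask
    instance_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(map(str, self.feature_names)))
        if values.ndim != 1 or values.shape[0] != 2 ** self.m:
            raise PreconditionError(
                f"incomplete subset-value table: expected {2 ** self.m} entries "
                f"for {self.m} features, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            mask = int(np.flatnonzero(~np.isfinite(values))[0])
            raise PreconditionError(
                "incomplete subset-value table: first missing/non-finite subset "
                f"is {mask_members(mask, self.feature_names)!r}"
            )

    @property
    def m(self) -> int:
        return len(self.feature_names)

    @property
    def n_subsets(self) -> int:
        return 2 ** self.m

    @property
    def null_value(self) -> float:
        """f(empty set)."""
        return float(self.values[0])

    @property
    def full_value(self) -> float:
        """f(M), the grand-coalition value."""
        return float(self.values[-1])

    def value(self, members) -> float:
        """Value of the subset given by an iterable of feature names."""
        return float(self.values[subset_mask(members, self.feature_names)])

    def is_exact(self, tol: float = 0.0) -> bool:
        """True when the table is an exact classification game: f(∅)=0 and
        every non-empty value is ±1."""
        if abs(self.values[0]) > tol:
            return False
        return bool(np.all(np.abs(np.abs(self.values[1:]) - 1.0) <= tol))

    def iter_canonical(self) -> Iterator[tuple[int, tuple[str, ...], float]]:
        """Yield (bitmask, member names, value) in canonical order."""
        for mask in canonical_subset_order(self.m):
            yield mask, mask_members(mask, self.feature_names), float(self.values[mask])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table in canonical order with bitmask, size, members
        and value columns."""
        rows = [
            {
                "instance_id": self.instance_id,
                "bitmask": mask,
                "size": len(members),
                "members": "|".join(members),
                "value": value,
            }
            for mask, members, value in self.iter_canonical()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dict(
        cls,
        value_of: dict[frozenset | tuple, float],
        feature_names: Sequence[str],
        instance_id: str = "",
    ) -> "SubsetValueTable":
        """Build a table from a mapping subset-of-names -> value; the mapping
        must cover all 2**m subsets."""
        feature_names = tuple(map(str, feature_names))
        values = np.full(2 ** len(feature_names), np.nan)
        for members, value in value_of.items():
            values[subset_mask(members, feature_names)] = value
        return cls(feature_names=feature_names, values=values, instance_id=instance_id)
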