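"""Canonical feature set of the serum proteomic 7NN test.

The diagnostic test combines intensities of eight mass-spectral features
(named by the approximate centre of their m/z region) with a 7-nearest-
neighbor classifier.  Published descriptions enumerate seven m/z positions
while using eight features throughout the analysis; the widely referenced
11,685 Da feature (a C-terminally truncated serum amyloid A isoform,
sometimes written 11,686) completes the set — see docs/methods.md.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .errors import InputError

#: Canonical feature names, in canonical order (ascending m/z).
CANONICAL_FEATURES: tuple[str, ...] = (
    "5843",
    "11445",
    "11529",
    "11685",
    "11759",
    "11903",
    "12452",
    "12579",
)

#: The probe pair whose unequal Shapley values mark a boundary instance.
DEFAULT_PROBE_PAIR: tuple[str, str] = ("11529", "11685")

#: Class labels and their numeric encoding (Poor = -1, Good = +1).
LABEL_ENCODING: dict[str, int] = {"Poor": -1, "Good": 1}
LABEL_DECODING: dict[int, str] = {-1: "Poor", 1: "Good", 0: "Indeterminate"}


def feature_indices(
    names: Iterable[str], feature_names: Sequence[str]
) -> list[int]:
    """Map feature names to their positions in ``feature_names``.

    Raises :class:`InputError` on an unknown name.
    """
    lookup = {f: i for i, f in enumerate(feature_names)}
    idx = []
    for name in names:
        name = str(name)
        if name not in lookup:
            raise InputError(
                f"unknown feature name {name!r}; known features: "
                f"{list(feature_names)}"
            )
        idx.append(lookup[name])
    return idx


def subset_mask(members: Iterable[str], feature_names: Sequence[str]) -> int:
    """Bitmask of a feature subset; bit ``i`` set iff ``feature_names[i]``
    is a member."""
    mask = 0
    for i in feature_indices(members, feature_names):
        mask |= 1 << i
    return mask


def mask_members(mask: int, feature_names: Sequence[str]) -> tuple[str, ...]:
    """Members of a bitmask subset, in canonical order."""
    return tuple(f for i, f in enumerate(feature_names) if mask >> i & 1)
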