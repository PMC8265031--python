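"""Per-feature explanation container shared by every method."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

#: Recognised method tags.
METHODS = (
    "exact",
    "kernel_shap",
    "gaussian_shap",
    "copula_shap",
    "lime_logistic",
    "lime_svm",
)


@dataclass
class Attribution:
    """Per-feature explanation values for one instance.

    ``phi`` maps each feature to its attribution (exact Shapley value, SHAP
    approximation, or LIME surrogate coefficient).  ``null_value`` is the
    null-set term (f(∅) for Shapley-type methods, the surrogate intercept
    for LIME); ``full_value`` is f(M) where defined.  ``meta`` records
    provenance such as seed and Monte-Carlo sample count.
    """

    instance_id: str
    method: str
    feature_names: tuple[str, ...]
    phi: np.ndarray
    null_value: float = 0.0
    full_value: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InputError(f"unknown method tag {self.method!r}; expected one of {METHODS}")
        self.feature_names = tuple(map(str, self.feature_names))
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.feature_names),):
            raise InputError("phi length does not match feature_names")

    def __getitem__(self, feature: str) -> float:
        try:
            return float(self.phi[self.feature_names.index(str(feature))])
        except ValueError:
            raise InputError(f"feature {feature!r} absent from attribution") from None

    def as_series(self) -> pd.Series:
        return pd.Series(self.phi, index=list(self.feature_names), name=self.instance_id)

    def to_frame(self) -> pd.DataFrame:
        """Long format: instance_id, method, feature, phi."""
        return pd.DataFrame(
            {
                "instance_id": self.instance_id,
                "method": self.method,
                "feature": list(self.feature_names),
                "phi": self.phi,
            }
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "instance_id": self.instance_id,
            "method": self.method,
            "phi": {f: float(v) for f, v in zip(self.feature_names, self.phi)},
            "null_value": float(self.null_value),
            "full_value": None if self.full_value is None else float(self.full_value),
            "meta": dict(self.meta),
        }


def attributions_to_frame(attributions: list[Attribution]) -> pd.DataFrame:
    """Concatenate attributions into one long-format DataFrame."""
    if not attributions:
        return pd.DataFrame(columns=["instance_id", "method", "feature", "phi"])
    return pd.concat([a.to_frame() for a in attributions], ignore_index=True)


def phi_matrix(attributions: list[Attribution]) -> pd.DataFrame:
    """Wide (instances x features) matrix of attribution values."""
    return pd.DataFrame(
        {a.instance_id: a.as_series() for a in attributions}
    ).T
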