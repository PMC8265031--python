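"""CSV/JSON readers and writers for the package's table dialects.

Reference sets and instance tables are plain CSVs with a header row
``sample_id,label,5843,11445,...`` (``label`` omitted or ignored for
instances; an optional ``replicate`` column tags technical replicates).
Every written file starts with a comment line embedding the seed and a
hash of the writing configuration, so equal configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd

from .attribution import Attribution, attributions_to_frame
from .errors import InputError
from .tables import SubsetValueTable


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_line(config: dict[str, Any] | None) -> str:
    config = config or {}
    seed = config.get("seed", "none")
    return f"# knnexplain config_hash={config_hash(config)} seed={seed}\n"


def write_csv(df: pd.DataFrame, path, config: dict[str, Any] | None = None,
              index: bool = False) -> None:
    """Write a DataFrame with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_line(config))
        df.to_csv(fh, index=index, lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"sample_id": str})


def write_reference_csv(X: pd.DataFrame, y: pd.Series, path,
                        config: dict[str, Any] | None = None) -> None:
    df = X.copy()
    df.insert(0, "label", y)
    df.insert(0, "sample_id", X.index)
    write_csv(df, path, config=config)


def read_reference_csv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a labeled reference set; raises with row/column context on
    malformed input."""
    df = read_csv(path)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    bad = ~df["label"].isin(["Good", "Poor"])
    if bad.any():
        row = df.index[bad][0]
        raise InputError(
            f"{path}: row {row}: label {df.loc[row, 'label']!r} is not Good/Poor"
        )
    X = df.drop(columns=["sample_id", "label"]).astype(float)
    X.index = df["sample_id"].astype(str)
    y = pd.Series(df["label"].to_numpy(), index=X.index, name="label")
    return X, y


def read_instances_csv(path) -> pd.DataFrame:
    """Read an instance table; returns a DataFrame indexed by sample_id
    with an optional ``replicate`` column and feature columns."""
    df = read_csv(path)
    if "sample_id" not in df.columns:
        raise InputError(f"{path}: missing required column 'sample_id'")
    df = df.drop(columns=[c for c in ("label",) if c in df.columns])
    df = df.set_index(df["sample_id"].astype(str)).drop(columns=["sample_id"])
    feature_cols = [c for c in df.columns if c != "replicate"]
    try:
        df[feature_cols] = df[feature_cols].astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric feature value ({exc})") from None
    return df


def write_attributions(
    attributions: list[Attribution], csv_path, json_path=None,
    config: dict[str, Any] | None = None
) -> None:
    """Long-format CSV ``instance_id,method,feature,phi`` plus a JSON
    mirror carrying null/full values and per-attribution metadata."""
    write_csv(attributions_to_frame(attributions), csv_path, config=config)
    if json_path is not None:
        payload = {
            "config_hash": config_hash(config or {}),
            "attributions": [a.to_dict() for a in attributions],
        }
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_attributions(csv_path) -> list[Attribution]:
    """Rebuild attributions from the long CSV (null/full values absent)."""
    df = read_csv(csv_path)
    out = []
    for (instance_id, method), group in df.groupby(
        ["instance_id", "method"], sort=False
    ):
        out.append(
            Attribution(
                instance_id=str(instance_id),
                method=str(method),
                feature_names=tuple(map(str, group["feature"])),
                phi=group["phi"].to_numpy(dtype=float),
            )
        )
    return out


def write_subset_table(table: SubsetValueTable, csv_path, json_path=None,
                       config: dict[str, Any] | None = None) -> None:
    """Export a subset-value table as CSV (bitmask, size, members, value);
    the JSON export mirrors the CSV rows."""
    df = table.to_frame()
    write_csv(df, csv_path, config=config)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(df.to_dict(orient="records"), indent=1)
        )
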