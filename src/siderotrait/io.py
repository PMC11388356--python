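"""CSV/YAML I/O with schema validation and column mapping.

Canonical tables
----------------
isolate CSV:  isolate_id, microcosm_id, group, replicate, isolate_type,
              copper, community_context, genus, siderophore
assay CSV:    isolate_id, a630, a630_ref, od600

Loaders accept a ``column_map`` ({canonical: actual}) so externally
deposited tables with different headers can be ingested without editing
the files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "ISOLATE_COLUMNS",
    "ASSAY_COLUMNS",
    "SchemaError",
    "read_isolates",
    "read_assays",
    "write_table",
    "read_config",
]

ISOLATE_COLUMNS = [
    "isolate_id",
    "microcosm_id",
    "group",
    "replicate",
    "isolate_type",
    "copper",
    "community_context",
    "genus",
    "siderophore",
]
#: columns the analyses actually require; the rest are carried when present
ISOLATE_REQUIRED = ["isolate_id", "replicate", "isolate_type", "copper", "siderophore"]

ASSAY_COLUMNS = ["isolate_id", "a630", "a630_ref", "od600"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _load_csv(path, column_map=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_isolates(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load and validate an isolate table."""
    df = _load_csv(path, column_map)
    missing = [c for c in ISOLATE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad = df.index[df["siderophore"].isna()]
    if len(bad):
        raise SchemaError(f"{path}: missing siderophore value at row {bad[0]}")
    types = set(df["isolate_type"].unique())
    unknown = types - {"community", "SBW25"}
    if unknown:
        raise SchemaError(
            f"{path}: unknown isolate_type value(s) {sorted(unknown)}; "
            "expected 'community' or 'SBW25'"
        )
    df["copper"] = df["copper"].astype(int)
    if not set(df["copper"].unique()) <= {0, 1}:
        raise SchemaError(f"{path}: column 'copper' must be a 0/1 indicator")
    return df


def read_assays(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load and validate a raw assay-read table."""
    df = _load_csv(path, column_map)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, cond in (("a630_ref", df["a630_ref"] <= 0), ("od600", df["od600"] <= 0)):
        bad = df.index[cond]
        if len(bad):
            raise SchemaError(f"{path}: column {col!r} must be positive (row {bad[0]})")
    return df


def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a CSV with an optional seed recorded in a header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_config(path) -> dict:
    """Read a YAML or JSON pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg
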