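"""Delimited-text feature tables and JSON selection reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import FeatureTable, SelectionResult, SelectionStep

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "write_selection_report",
    "read_selection_report",
]


def read_feature_table(path, label_column: str = "class") -> FeatureTable:
    """Read a CSV/TSV table (header row required) into a FeatureTable.

    Every column except ``label_column`` must be numeric; errors name the
    offending row or column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed delimited text ({e})") from e
    if label_column not in df.columns:
        raise ValueError(f"{path}: label column {label_column!r} not found "
                         f"(columns: {list(df.columns)})")
    labels = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        vals = pd.to_numeric(feats[col], errors="coerce")
        bad = vals.isna() & feats[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        feats[col] = vals
    return FeatureTable(
        features=feats.to_numpy(dtype=float),
        labels=labels,
        feature_names=[str(c) for c in feats.columns],
        instance_ids=[str(i) for i in df.index],
    )


def write_feature_table(table: FeatureTable, path, label_column: str = "class") -> None:
    df = pd.DataFrame(table.features, columns=table.feature_names)
    df[label_column] = table.labels
    df.to_csv(path, index=False)


def write_selection_report(result: SelectionResult, path, *, feature_names=None,
                           config: dict | None = None, seed: int | None = None) -> None:
    """Serialize a selection trace to JSON (selected indices/names, per-step
    k/chosen/J/D/R/Phi/cv_accuracy, stopping reason, config echo, seed)."""
    payload = {
        "selected": list(map(int, result.selected)),
        "selected_names": ([feature_names[i] for i in result.selected]
                           if feature_names else None),
        "steps": [dataclasses.asdict(s) for s in result.steps],
        "stopped_reason": result.stopped_reason,
        "config": config,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_selection_report(path) -> SelectionResult:
    payload = json.loads(Path(path).read_text())
    steps = [SelectionStep(**{k: v for k, v in s.items()}) for s in payload["steps"]]
    return SelectionResult(selected=[int(i) for i in payload["selected"]],
                           steps=steps, stopped_reason=payload["stopped_reason"])
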