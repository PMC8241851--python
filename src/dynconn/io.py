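"""Readers and writers for the package's plain-text dialects.

All tabular files are tab-separated with a header row. Matrices carry region
names as both header and row names. Events tables use the three-column
``onset / duration / condition`` layout with times in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "read_motion_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_json",
    "read_json",
]


def write_timeseries_tsv(path, values, region_names) -> None:
    """Write a T x M region time-series table (header = region names)."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values, columns=list(region_names))
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path):
    """Read a region time-series table; returns (values, region_names)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_events_tsv(path, events: pd.DataFrame) -> None:
    cols = ["onset", "duration", "condition"]
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    events[cols].to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "condition"):
        if col not in df.columns:
            raise ValueError(f"events file {path} lacks required column {col!r}")
    return df


def read_motion_tsv(path) -> np.ndarray:
    """Read a T x 6 motion-parameter table; unnamed columns are accepted."""
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python", header=None)
    # tolerate a header row of non-numeric labels
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        arr = df.iloc[1:].to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got shape {arr.shape}")
    return arr


def write_matrix_tsv(path, matrix, names) -> None:
    matrix = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(matrix, index=list(names), columns=list(names))
    df.to_csv(path, sep="\t", index=True, index_label="region")


def read_matrix_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
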