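"""Readers/writers for the long-format and matrix CSV interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import FeatureTable
from .longitudinal import LongitudinalSeries

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_sample",
    "write_provenance",
]

_LONG_COLUMNS = ("subject", "group", "time", "value")


def read_long_csv(path) -> list:
    """Parse a long-format CSV (subject, group, time, value) into series."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            lines = (df.index[bad | df[col].isna()] + 2).tolist()
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["subject", "time"], keep=False)
    if dup.any():
        first = df.loc[dup, ["subject", "time"]].iloc[0]
        raise ValueError(
            f"{path}: duplicated (subject, time) pair "
            f"({first['subject']!r}, {first['time']})"
        )
    series = []
    for subject, sub in df.groupby("subject", sort=False):
        sub = sub.sort_values("time")
        groups = sub["group"].unique()
        if len(groups) > 1:
            raise ValueError(f"{path}: subject {subject!r} has multiple groups")
        series.append(
            LongitudinalSeries(
                subject=str(subject),
                group=str(groups[0]),
                times=sub["time"].to_numpy(dtype=float),
                values=sub["value"].to_numpy(dtype=float),
            )
        )
    return series


def write_long_csv(series, path) -> None:
    rows = [
        {"subject": s.subject, "group": s.group, "time": t, "value": v}
        for s in series
        for t, v in zip(s.times, s.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_matrix_csv(matrix_path, labels_path) -> FeatureTable:
    """Read a samples-by-features matrix CSV plus a one-column labels CSV."""
    mat = pd.read_csv(matrix_path)
    if mat.empty:
        raise ValueError(f"{matrix_path}: no data rows")
    labels = pd.read_csv(labels_path)
    if labels.shape[1] < 1:
        raise ValueError(f"{labels_path}: no label column")
    lab = labels["label"] if "label" in labels.columns else labels.iloc[:, 0]
    if len(lab) != len(mat):
        raise ValueError(
            f"labels ({len(lab)} rows) do not match matrix ({len(mat)} rows)"
        )
    values = mat.to_numpy(dtype=float)
    return FeatureTable(
        values=values,
        feature_names=list(mat.columns),
        labels=lab.to_numpy(),
    )


def write_matrix_csv(table: FeatureTable, matrix_path, labels_path) -> None:
    pd.DataFrame(table.values, columns=table.feature_names).to_csv(
        matrix_path, index=False, float_format="%.12g"
    )
    pd.DataFrame({"label": table.labels}).to_csv(labels_path, index=False)


def read_sample(path) -> np.ndarray:
    """One-column numeric text/CSV sample."""
    df = pd.read_csv(path, header=None)
    first = df.iloc[0, 0]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    values = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"{path}: empty sample")
    return values


def write_provenance(path, **fields) -> None:
    """JSON sidecar recording seed, candidate order, and other run settings."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(fields, indent=2, default=_default))
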