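"""Reading and writing labeled feature tables and result reports.

Feature tables are CSV/TSV files with a header row of feature IDs; the class
label lives either in a designated column or in a separate one-column labels
file aligned by row order.  Malformed input (missing cells, non-numeric
values, duplicate feature IDs) is rejected with the offending location.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ranking import LabeledTable

__all__ = ["read_table", "write_report"]


def _sep_for(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    # sniff the header line
    head = path.open().readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_table(
    path,
    label_col: "str | None" = None,
    labels_path=None,
    sep: "str | None" = None,
) -> LabeledTable:
    """Load a samples x features table with binary labels.

    Exactly one of ``label_col`` (column inside the table) or ``labels_path``
    (separate file, one label per row) must be given.
    """
    path = Path(path)
    if (label_col is None) == (labels_path is None):
        raise ValueError("give exactly one of label_col or labels_path")
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0)

    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(f"{path}: label column {label_col!r} not found")
        labels = df[label_col].to_numpy()
        feats = df.drop(columns=[label_col])
    else:
        labels = (
            pd.read_csv(labels_path, header=None).iloc[:, 0].to_numpy()
        )
        if len(labels) != len(df):
            raise ValueError(
                f"{labels_path}: {len(labels)} labels for {len(df)} rows"
            )
        feats = df

    dup = feats.columns[feats.columns.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate feature IDs {sorted(set(dup))}")
    for col in feats.columns:
        bad = feats.index[pd.to_numeric(feats[col], errors="coerce").isna()
                          & feats[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric cell at row {bad[0]!r}, column {col!r}"
            )
    na = feats.isna()
    if na.to_numpy().any():
        row = feats.index[na.any(axis=1)][0]
        col = feats.columns[na.loc[row].to_numpy().argmax()]
        raise ValueError(f"{path}: missing cell at row {row!r}, column {col!r}")
    return LabeledTable(
        values=feats.to_numpy(dtype=float),
        labels=labels,
        feature_ids=[str(c) for c in feats.columns],
        sample_ids=[str(i) for i in feats.index],
    )


def write_table(table: LabeledTable, path, label_col: str = "label") -> None:
    path = Path(path)
    table.to_dataframe(label_col).to_csv(path, sep=_sep_for(path))


def write_report(report: dict, path) -> None:
    """Write a result record as JSON plus a flat CSV twin next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    flat = _flatten(report)
    pd.DataFrame(
        [{"key": k, "value": v} for k, v in flat.items()]
    ).to_csv(path.with_suffix(".csv"), index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(map(str, obj))
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _flatten(d, prefix="") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        elif isinstance(v, (list, tuple, np.ndarray, set, frozenset)):
            out[key] = json.dumps(v, default=_jsonable)
        else:
            out[key] = v
    return out
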