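"""Delimited-text readers and writers for every pipeline artefact.

All formats are plain TSV so fixtures stay diffable and language-agnostic:
per-subject time series (one row per timepoint, header = node names), the
subject table (subject_id, group, age, sex, plus score columns), the node
table (name, lobe, hemisphere), and square matrices with a node-name header
row and column.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ROITimeSeries

__all__ = [
    "load_node_table",
    "read_timeseries",
    "write_timeseries",
    "read_timeseries_dir",
    "read_subject_table",
    "write_subject_table",
    "read_matrix",
    "write_matrix",
]

REQUIRED_SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex")
GROUP_LABELS = ("case", "control")


def load_node_table(path: str | Path | None = None) -> pd.DataFrame:
    """Node/ROI table (name, lobe, hemisphere); defaults to the packaged
    AAL-based 112-region set."""
    if path is None:
        ref = resources.files("fcnet.data").joinpath("aal112_nodes.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    missing = {"name", "lobe", "hemisphere"} - set(table.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    if table["name"].duplicated().any():
        raise ValueError("node table has duplicate region names")
    return table


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.node_names).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_timeseries(path: str | Path, node_names: list[str]) -> ROITimeSeries:
    """Read one subject's series, re-ordering columns to node-table order."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    missing = [n for n in node_names if n not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing node column(s) {missing[:5]}")
    frame = frame[node_names]
    if frame.isna().any().any():
        raise ValueError(f"{path.name}: NaN cells in time series")
    data = frame.to_numpy(dtype=float)
    dead = [node_names[i] for i in np.flatnonzero(data.std(axis=0) == 0)]
    if dead:
        raise ValueError(f"{path.name}: constant column(s) {dead}")
    return ROITimeSeries(subject_id=path.stem, data=data, node_names=list(node_names))


def read_timeseries_dir(path: str | Path, node_table: pd.DataFrame) -> list[ROITimeSeries]:
    """All per-subject series in a directory (*.tsv), sorted by subject id."""
    path = Path(path)
    names = list(node_table["name"])
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv time-series files under {path}")
    return [read_timeseries(f, names) for f in files]


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Subject metadata table; unknown numeric columns are kept as scores."""
    table = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_SUBJECT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject id(s): {dup}")
    bad = sorted(set(table["group"]) - set(GROUP_LABELS))
    if bad:
        raise ValueError(f"unknown group label(s) {bad}; expected {GROUP_LABELS}")
    return table.sort_values("subject_id", ignore_index=True)


def write_subject_table(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_matrix(weights: np.ndarray, node_names: list[str], path: str | Path) -> None:
    """Square matrix with node-name header row and index column."""
    pd.DataFrame(weights, index=node_names, columns=node_names).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{Path(path).name}: row and column labels disagree")
    return frame.to_numpy(dtype=float), list(frame.columns)
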