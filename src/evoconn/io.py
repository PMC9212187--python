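"""Delimited-text input/output: time series, connectivity matrices, manifests.

A cohort on disk is a manifest TSV (columns: subject_id, path, group) plus
one time-series TSV per subject, T rows x N ROI columns with a header row
of ROI labels.  Connectivity matrices are square TSVs with ROI labels on
both axes.  Everything round-trips losslessly at float precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, MatrixKind, RoiTimeSeries

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_connectivity_tsv",
    "read_connectivity_tsv",
    "write_cohort",
    "read_cohort",
]


def write_timeseries_tsv(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.data, columns=list(ts.roi_labels)).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path, subject_id: str | None = None, dt: float = 3.0) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    sid = subject_id if subject_id is not None else Path(path).stem
    return RoiTimeSeries(sid, df.to_numpy(float), [str(c) for c in df.columns], dt=dt)


def write_connectivity_tsv(c: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(c.values, index=list(c.roi_labels), columns=list(c.roi_labels))
    df.to_csv(path, sep="\t", index_label="roi")


def read_connectivity_tsv(path, kind: str = "fisher_z") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("connectivity matrix row and column labels differ")
    return ConnectivityMatrix(df.to_numpy(float), [str(c) for c in df.columns], MatrixKind(kind))


def write_cohort(
    cohort: Sequence[RoiTimeSeries],
    labels: Sequence[int],
    out_dir,
    group_names: tuple[str, str] = ("group0", "group1"),
) -> Path:
    """Write per-subject TSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, lab in zip(cohort, labels):
        fname = f"{ts.subject_id}.tsv"
        write_timeseries_tsv(ts, out_dir / fname)
        rows.append({"subject_id": ts.subject_id, "path": fname, "group": group_names[int(lab)], "dt": ts.dt})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(
    manifest_path, group_names: tuple[str, str] | None = None
) -> tuple[list[RoiTimeSeries], np.ndarray, tuple[str, str]]:
    """Load a manifest and its per-subject time series.

    Returns (cohort, 0/1 labels, group_names); paths in the manifest are
    resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    for col in ("subject_id", "path", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing the {col!r} column")
    groups = list(dict.fromkeys(df["group"]))
    if group_names is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly two groups in manifest, found {groups}")
        group_names = (groups[0], groups[1])
    label_map = {group_names[0]: 0, group_names[1]: 1}
    cohort: list[RoiTimeSeries] = []
    labels: list[int] = []
    for _, row in df.iterrows():
        dt = float(row["dt"]) if "dt" in df.columns else 3.0
        ts = read_timeseries_tsv(manifest_path.parent / row["path"], str(row["subject_id"]), dt=dt)
        cohort.append(ts)
        labels.append(label_map[row["group"]])
    return cohort, np.asarray(labels, dtype=int), group_names
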