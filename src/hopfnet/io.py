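"""Delimited-text IO for connectivity matrices and ROI time series.

Matrices travel as whitespace-delimited text with a JSON sidecar carrying
the role and labels; time series as text with a header row of ROI labels.
Binary (.npy) copies are written alongside for fast reloading.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import ConnMatrix, RoiTimeSeries

__all__ = [
    "write_conn_matrix",
    "read_conn_matrix",
    "write_timeseries",
    "read_timeseries",
]


def write_conn_matrix(path: str | Path, m: ConnMatrix) -> Path:
    """Write a matrix as text plus a ``<path>.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, m.values)
    sidecar = {"role": m.role, "labels": m.labels}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    return path


def read_conn_matrix(path: str | Path) -> ConnMatrix:
    path = Path(path)
    values = np.loadtxt(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return ConnMatrix(
        values=values, role=meta.get("role", "SC"), labels=meta.get("labels")
    )


def write_timeseries(path: str | Path, ts: RoiTimeSeries) -> Path:
    """ROIs in rows; the header records labels, TR, subject and state."""
    path = Path(path)
    header = json.dumps(
        {"roi_labels": ts.roi_labels, "tr": ts.tr, "subject": ts.subject, "state": ts.state}
    )
    np.savetxt(path, ts.data, header=header)
    return path


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    return RoiTimeSeries(
        data=data,
        tr=meta.get("tr", 1.0),
        subject=meta.get("subject", ""),
        state=meta.get("state", ""),
        roi_labels=meta.get("roi_labels"),
    )
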