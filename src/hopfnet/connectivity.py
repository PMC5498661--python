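"""Functional connectivity and Kuramoto synchrony metrics.

FC is the matrix of Pearson correlations between ROI signals over the whole
recording.  Group FC averages subject matrices through Fisher's r-to-z
transform.  Global phase locking is quantified by the Kuramoto order
parameter R(t) = |mean_k exp(i phi_k(t))|; its temporal mean is termed
synchrony and its temporal SD metastability.
"""

from __future__ import annotations

import numpy as np

from .containers import ConnMatrix, FilterSpec, RoiTimeSeries, SyncStats
from .exceptions import DegenerateSignalError, ShapeError, TransformDomainError
from .signals import edge_trim_samples, hilbert_phases, preprocess

__all__ = [
    "compute_fc",
    "group_average_fc",
    "fc_summary",
    "node_strength",
    "kuramoto",
    "sync_stats",
    "phase_locking_stats",
    "fc_distance",
]


def compute_fc(ts: RoiTimeSeries) -> ConnMatrix:
    """Pearson-correlation FC matrix of one recording.

    Correlations are computed over the full duration (no windowing); the
    result is symmetrised and its diagonal forced to exactly 1.
    """
    if ts.n_samples < 3:
        raise ShapeError(f"need at least 3 samples for correlation, got {ts.n_samples}")
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise DegenerateSignalError(
            "zero-variance ROI(s) in FC computation: "
            + ", ".join(ts.roi_labels[i] for i in bad[:5])
        )
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnMatrix(values=r, role="FC", labels=list(ts.roi_labels))


def group_average_fc(fcs: list[ConnMatrix]) -> ConnMatrix:
    """Fisher-average a list of FC matrices: atanh -> mean -> tanh.

    All off-diagonal entries must lie strictly inside (-1, 1); +-1 has no
    finite z-value and raises :class:`TransformDomainError`.
    """
    if not fcs:
        raise ShapeError("empty FC list")
    n = fcs[0].n
    if any(fc.n != n for fc in fcs):
        raise ShapeError("FC matrices have inconsistent dimensions")
    stack = np.stack([fc.values for fc in fcs])
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(stack[:, off]) >= 1.0):
        raise TransformDomainError("off-diagonal |r| = 1 cannot be Fisher-transformed")
    z = np.arctanh(np.where(off, stack, 0.0))
    mean = np.tanh(z.mean(axis=0))
    np.fill_diagonal(mean, 1.0)
    return ConnMatrix(values=mean, role="FC", labels=fcs[0].labels)


def fc_summary(fc: ConnMatrix) -> tuple[float, float]:
    """Mean and population SD of the strictly-upper-triangle FC entries."""
    if fc.n < 2:
        raise ShapeError("FC summary needs at least a 2x2 matrix")
    upper = fc.upper_triangle()
    return float(upper.mean()), float(upper.std())


def node_strength(m: ConnMatrix | np.ndarray) -> np.ndarray:
    """Per-node sum of connection weights, diagonal excluded."""
    v = m.values if isinstance(m, ConnMatrix) else np.asarray(m, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ShapeError("node_strength requires a square matrix")
    return v.sum(axis=1) - np.diag(v)


def kuramoto(phases: np.ndarray) -> np.ndarray:
    """Kuramoto order parameter R(t) of an ROI x time phase array.

    R(t) is the modulus of the average unit phasor across nodes at each
    time point: 0 is complete asynchrony, 1 complete phase locking.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[0] < 1 or phases.size == 0:
        raise ShapeError("phases must be a non-empty 2-D array (ROI x time)")
    r = np.abs(np.exp(1j * phases).mean(axis=0))
    return np.minimum(r, 1.0)


def sync_stats(r: np.ndarray) -> SyncStats:
    """Synchrony (temporal mean) and metastability (temporal population SD)
    of a Kuramoto order-parameter series."""
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ShapeError("order-parameter series must be 1-D with length >= 2")
    return SyncStats(float(r.mean()), float(r.std()))


def phase_locking_stats(
    ts: RoiTimeSeries, band: FilterSpec, preprocessed: bool = False
) -> SyncStats:
    """Synchrony/metastability of one recording.

    Convenience chain: band-pass preprocess (unless ``preprocessed``),
    Hilbert phases, edge trimming, Kuramoto order parameter, temporal
    statistics.
    """
    clean = ts if preprocessed else preprocess(ts, band)
    phases = hilbert_phases(clean)
    trim = edge_trim_samples(band, ts.tr)
    if phases.shape[1] > 2 * trim + 2:
        phases = phases[:, trim:-trim]
    return sync_stats(kuramoto(phases))


def fc_distance(fc_a: ConnMatrix, fc_b: ConnMatrix) -> float:
    """Euclidean distance between the strictly-upper-triangle FC vectors."""
    if fc_a.n != fc_b.n:
        raise ShapeError("FC matrices must share dimensions")
    return float(np.linalg.norm(fc_a.upper_triangle() - fc_b.upper_triangle()))
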