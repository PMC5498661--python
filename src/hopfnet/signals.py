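"""Narrowband preprocessing and instantaneous phase extraction.

The analysis operates on slow BOLD fluctuations restricted to a narrow band
(0.04-0.07 Hz by default).  Each ROI signal is detrended, demeaned,
band-pass filtered with a zero-phase Butterworth filter, and z-scored;
instantaneous phases are then obtained from the analytic signal via the
Hilbert transform.  Phases are only meaningful for narrowband signals,
hence filtering is a precondition of :func:`hilbert_phases`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps

from .containers import FilterSpec, RoiTimeSeries
from .exceptions import DegenerateSignalError, ParameterError

__all__ = [
    "design_bandpass",
    "preprocess",
    "hilbert_phases",
    "edge_trim_samples",
]


def design_bandpass(spec: FilterSpec, tr: float) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass for sampling
    interval ``tr``.

    ``spec.order`` is the pole count of the band-pass, so the underlying
    prototype order is ``spec.order // 2``.
    """
    nyquist = 0.5 / tr
    if not spec.high < nyquist:
        raise ParameterError(
            f"high corner {spec.high} Hz must be below the Nyquist frequency "
            f"{nyquist:.4g} Hz for TR {tr} s"
        )
    return sps.butter(
        spec.order // 2, [spec.low, spec.high], btype="bandpass",
        fs=1.0 / tr, output="sos",
    )


def _check_variance(data: np.ndarray, labels: list[str], what: str) -> None:
    sd = data.std(axis=1)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise DegenerateSignalError(
            f"zero-variance signal {what} in ROI(s): "
            + ", ".join(labels[i] for i in bad[:5])
        )


def preprocess(ts: RoiTimeSeries, spec: FilterSpec) -> RoiTimeSeries:
    """Detrend, demean, zero-phase band-pass filter and z-score each ROI.

    The linear detrend removes slow drifts; demeaning is subsumed by the
    final z-score (population SD).  Filtering is forward-backward
    (``sosfiltfilt``), which doubles the attenuation and cancels group
    delay — a requirement for downstream phase analysis.

    Raises
    ------
    DegenerateSignalError
        If any ROI is constant before, or has zero variance after,
        filtering.
    """
    _check_variance(ts.data, ts.roi_labels, "before filtering")
    sos = design_bandpass(spec, ts.tr)
    detrended = sps.detrend(ts.data, axis=1, type="linear")
    filtered = sps.sosfiltfilt(sos, detrended, axis=1)
    _check_variance(filtered, ts.roi_labels, "after filtering")
    z = (filtered - filtered.mean(axis=1, keepdims=True)) / filtered.std(axis=1, keepdims=True)
    return ts.with_data(z)


def hilbert_phases(ts: RoiTimeSeries) -> np.ndarray:
    """Instantaneous phase of each ROI's analytic signal, in [-pi, pi].

    The analytic signal is a(t) = x(t) + i H[x(t)]; the caller is expected
    to have band-limited ``ts`` (see :func:`preprocess`) so the phase is
    well defined.

    Returns
    -------
    ndarray, shape (n_rois, n_samples)
    """
    _check_variance(ts.data, ts.roi_labels, "(all-zero row)")
    analytic = sps.hilbert(ts.data, axis=1)
    return np.angle(analytic)


def edge_trim_samples(spec: FilterSpec, tr: float) -> int:
    """Samples to discard at each end before phase-based statistics.

    Filter and Hilbert edge transients extend over roughly one period of
    the slowest band component, i.e. ceil(1 / (low * tr)) samples.
    """
    return math.ceil(1.0 / (spec.low * tr))
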