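"""Shared data containers.

The pipeline passes around a small set of typed containers: ROI-by-time
recordings, role-tagged connectivity matrices, filter/stimulus settings and
the Hopf model's working-point parameters.  Containers validate their
invariants on construction so downstream code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .exceptions import ParameterError, ShapeError

CONN_ROLES = ("FC", "SC", "EC")

_SYM_TOL = 1e-10


@dataclass
class RoiTimeSeries:
    """One subject-state recording: an ROI x time matrix plus its TR.

    Parameters
    ----------
    data : ndarray, shape (n_rois, n_samples)
        BOLD-like signals, one row per region (arbitrary units).
    tr : float
        Repetition time (sampling interval) in seconds.
    subject, state : str
        Labels identifying the recording within a cohort.
    roi_labels : list of str, optional
        Region names; defaults to ``roi000, roi001, ...``.
    """

    data: np.ndarray
    tr: float
    subject: str = ""
    state: str = ""
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError(f"data must be 2-D (ROI x time), got {self.data.ndim}-D")
        if self.data.shape[0] < 1:
            raise ShapeError("at least one ROI is required")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("time series contain non-finite values")
        if not self.tr > 0:
            raise ParameterError(f"tr must be positive, got {self.tr}")
        if self.roi_labels is None:
            self.roi_labels = [f"roi{i:03d}" for i in range(self.data.shape[0])]
        elif len(self.roi_labels) != self.data.shape[0]:
            raise ShapeError("roi_labels length does not match ROI count")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz (1/TR)."""
        return 1.0 / self.tr

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        """Copy of this recording with ``data`` replaced, labels retained."""
        return replace(self, data=data)

    def with_state(self, state: str) -> "RoiTimeSeries":
        """Relabelled view sharing the same underlying data array."""
        return replace(self, state=state)


@dataclass
class ConnMatrix:
    """Square connectivity matrix tagged by role (FC, SC or EC).

    Role-specific invariants are enforced on construction:

    * all roles: square, symmetric (within 1e-10);
    * FC: entries in [-1, 1], unit diagonal;
    * SC/EC: nonnegative entries, (near-)zero diagonal.  A tiny epsilon
      diagonal tolerance accommodates the 2^-52 link floor used in the
      effective-connectivity estimation.
    """

    values: np.ndarray
    role: str
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.role not in CONN_ROLES:
            raise ParameterError(f"role must be one of {CONN_ROLES}, got {self.role!r}")
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"connectivity matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ParameterError("connectivity matrix contains non-finite values")
        if np.max(np.abs(v - v.T), initial=0.0) > _SYM_TOL:
            raise ShapeError("connectivity matrix is not symmetric (tol 1e-10)")
        if self.role == "FC":
            if np.any(v < -1.0 - 1e-9) or np.any(v > 1.0 + 1e-9):
                raise ParameterError("FC entries must lie in [-1, 1]")
            if np.max(np.abs(np.diag(v) - 1.0), initial=0.0) > 1e-8:
                raise ParameterError("FC diagonal must be 1")
        else:
            if np.any(v < 0.0):
                raise ParameterError(f"{self.role} entries must be nonnegative")
            if np.max(np.abs(np.diag(v)), initial=0.0) > 1e-8:
                raise ParameterError(f"{self.role} diagonal must be (near) zero")
        if self.labels is not None and len(self.labels) != v.shape[0]:
            raise ShapeError("labels length does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangle entries as a flat vector (diagonal excluded)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


class SyncStats(NamedTuple):
    """Temporal mean (synchrony) and SD (metastability) of the Kuramoto
    order parameter R(t)."""

    synchrony: float
    metastability: float


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: corner frequencies in Hz and filter order.

    ``order`` counts the poles of the band-pass (the default 6 matches a
    sixth-order Butterworth); the filter is applied forward-backward, so the
    effective attenuation is squared and the net phase response is zero.
    """

    low: float = 0.04
    high: float = 0.07
    order: int = 6

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ParameterError(f"need 0 < low < high, got ({self.low}, {self.high})")
        if self.order < 2 or self.order % 2:
            raise ParameterError("order must be an even integer >= 2")


@dataclass(frozen=True)
class StimulusSpec:
    """Complex sinusoidal forcing F * exp(i * omega_f * t) applied to a node.

    ``duration`` (seconds) may be 0 to let the integrator choose a horizon
    long enough for the forced amplitude to equilibrate.
    """

    F: float
    omega_f: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ParameterError("forcing amplitude F must be >= 0")


@dataclass
class HopfParams:
    """Working point and integration settings of the Hopf network model.

    a : bifurcation parameter, uniform over nodes (a < 0: damped noisy
        oscillations; a > 0: limit cycle of amplitude sqrt(a)).
    G : global coupling scaling all structural links.
    omega : intrinsic angular frequencies per node (rad/s).
    beta : additive Gaussian noise scale (0.04 by default).
    dt : Euler step (seconds); the convention is dt = 0.1 * TR / 2.
    n_steps : total integration steps including the transient.
    downsample : integration steps per output sample (one sample per TR).
    transient_steps : initial steps discarded before sampling.
    seed : integer seeding both the initial state and the noise stream.
    """

    a: float
    G: float
    omega: np.ndarray
    beta: float = 0.04
    dt: float = 0.104
    n_steps: int = 0
    downsample: int = 20
    transient_steps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if self.downsample < 1:
            raise ParameterError("downsample must be >= 1")
        if self.n_steps <= self.transient_steps:
            raise ParameterError("n_steps must exceed transient_steps")

    @classmethod
    def for_tr(
        cls,
        a: float,
        G: float,
        omega: np.ndarray,
        tr: float,
        n_volumes: int,
        transient_volumes: int = 20,
        beta: float = 0.04,
        seed: int = 0,
    ) -> "HopfParams":
        """Build parameters so the output has ``n_volumes`` samples at TR
        resolution, after discarding ``transient_volumes`` TRs, with the
        dt = 0.1 * TR / 2 step convention."""
        dt = 0.1 * tr / 2.0
        downsample = max(1, round(tr / dt))
        transient_steps = transient_volumes * downsample
        n_steps = transient_steps + n_volumes * downsample
        return cls(
            a=a, G=G, omega=omega, beta=beta, dt=dt,
            n_steps=n_steps, downsample=downsample,
            transient_steps=transient_steps, seed=seed,
        )

    @property
    def n_nodes(self) -> int:
        return self.omega.shape[0]

    @property
    def n_keep(self) -> int:
        """Number of retained output samples."""
        return (self.n_steps - self.transient_steps) // self.downsample

    @property
    def tr(self) -> float:
        """Output sampling interval in seconds."""
        return self.dt * self.downsample


@dataclass
class SimOutput:
    """Simulation result: real part x at output resolution, and optionally
    the full-resolution complex state for single-node analyses."""

    x: np.ndarray            # (n_nodes, n_keep)
    tr: float                # output sampling interval, seconds
    z: np.ndarray | None = None   # optional full-resolution complex state

    def as_timeseries(self, subject: str = "sim", state: str = "model") -> RoiTimeSeries:
        return RoiTimeSeries(data=self.x, tr=self.tr, subject=subject, state=state)
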