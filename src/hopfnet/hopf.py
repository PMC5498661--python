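"""The Hopf whole-brain model: single-node normal form, coupled network,
intrinsic-frequency estimation, and the forced-node response analysis.

Each region j follows the normal form of a supercritical Hopf bifurcation,

    dz_j/dt = z_j (a + i w_j) - z_j |z_j|^2 + beta eta_j(t),

so that a < 0 gives a stable focus (noise-driven damped oscillations) and
a > 0 a limit cycle of amplitude sqrt(a) at frequency w_j / 2pi.  Nodes are
coupled diffusively through the structural matrix C with a global gain G
(applied to both real and imaginary parts); the simulated BOLD signal is
the real part x_j, sampled on the TR grid.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate as spi
from scipy import signal as sps
from scipy import stats

from ._integrators import integrate_network, integrate_node
from .containers import (
    ConnMatrix,
    FilterSpec,
    HopfParams,
    RoiTimeSeries,
    SimOutput,
    StimulusSpec,
)
from .exceptions import (
    DegenerateSpectrumError,
    IntegrationError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "simulate_node",
    "simulate_network",
    "estimate_intrinsic_frequencies",
    "response_amplitude",
    "power_law_exponent",
]


def _initial_state(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random initial condition in [-0.1, 0.1]^2 per node."""
    rng = np.random.default_rng(seed)
    init = rng.uniform(-0.1, 0.1, size=(2, n))
    return init[0], init[1]


def _noise_seed(seed: int) -> int:
    # numba's legacy RNG wants a positive 32-bit seed
    return int(seed) % (2**31 - 1)


def simulate_node(params: HopfParams, stim: StimulusSpec | None = None) -> SimOutput:
    """Integrate a single Hopf node (Euler-Maruyama), optionally forced.

    Returns the full-resolution trajectory in ``z`` and the x variable
    downsampled per ``params``.  With ``beta = 0`` the run is deterministic.
    """
    if params.n_nodes != 1:
        raise ShapeError("simulate_node expects a single-node parameter set")
    f_amp = 0.0 if stim is None else stim.F
    f_omega = 0.0 if stim is None else stim.omega_f
    x0, y0 = _initial_state(1, params.seed)
    xs, ys, bad = integrate_node(
        params.a, float(params.omega[0]), params.beta, params.dt,
        params.n_steps, _noise_seed(params.seed),
        float(x0[0]), float(y0[0]), f_amp, f_omega,
    )
    if bad >= 0:
        raise IntegrationError(f"single-node integration blew up at step {bad}", step=bad)
    z = xs + 1j * ys
    keep = xs[params.transient_steps:][params.downsample - 1:: params.downsample]
    return SimOutput(x=keep[None, :], tr=params.tr, z=z)


def simulate_network(params: HopfParams, sc: ConnMatrix | np.ndarray) -> SimOutput:
    """Integrate the coupled Hopf network on a structural matrix.

    The caller decides whether ``sc`` is raw or prepared/pre-scaled; the
    matrix is used as given.  The transient is discarded and the real part
    x is returned at TR resolution.  Identical parameters (including seed)
    give bit-identical output.
    """
    C = sc.values if isinstance(sc, ConnMatrix) else np.asarray(sc, dtype=float)
    if C.shape[0] != C.shape[1] or C.shape[0] != params.n_nodes:
        raise ShapeError(
            f"structural matrix {C.shape} does not match {params.n_nodes} nodes"
        )
    # per-node edge lists (ascending neighbour index) skip structural zeros
    cols = [np.flatnonzero(C[:, j]) for j in range(C.shape[1])]
    offsets = np.zeros(C.shape[0] + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([c.size for c in cols])
    nb_idx = (
        np.concatenate(cols).astype(np.int64)
        if offsets[-1] else np.empty(0, dtype=np.int64)
    )
    nb_w = C[nb_idx, np.repeat(np.arange(C.shape[1]), np.diff(offsets))]
    x0, y0 = _initial_state(params.n_nodes, params.seed)
    out, bad = integrate_network(
        params.a, params.omega, params.G, offsets, nb_idx,
        np.ascontiguousarray(nb_w),
        params.beta, params.dt, params.n_steps, params.downsample,
        params.transient_steps, _noise_seed(params.seed), x0, y0,
    )
    if bad >= 0:
        raise IntegrationError(f"network integration blew up at step {bad}", step=bad)
    return SimOutput(x=out, tr=params.tr)


def estimate_intrinsic_frequencies(
    group: list[RoiTimeSeries], band: FilterSpec
) -> np.ndarray:
    """Per-node intrinsic angular frequencies from band-limited data.

    For each subject and ROI the spectral peak inside [low, high] Hz is
    located on the periodogram; peak frequencies are averaged across
    subjects per ROI, clipped to the band, and returned as 2*pi*f (rad/s).
    ``group`` should contain already band-pass-filtered recordings.
    """
    if not group:
        raise ShapeError("empty group")
    n = group[0].n_rois
    peaks = np.empty((len(group), n))
    for s, ts in enumerate(group):
        freqs, pxx = sps.periodogram(ts.data, fs=ts.fs, axis=1)
        in_band = (freqs >= band.low) & (freqs <= band.high)
        if not np.any(in_band):
            raise DegenerateSpectrumError("no spectral estimate inside the band")
        band_p = pxx[:, in_band]
        if np.max(band_p) <= 0 or np.allclose(band_p, band_p[:, :1]):
            raise DegenerateSpectrumError("flat spectrum inside the band")
        peaks[s] = freqs[in_band][np.argmax(band_p, axis=1)]
    mean_f = np.clip(peaks.mean(axis=0), band.low, band.high)
    return 2.0 * np.pi * mean_f


def _rotating_frame_rhs(t, u, a, domega, f):
    # u = (Re, Im) of z e^{-i w_F t}: du/dt = (a + i domega) u - |u|^2 u + F
    ur, ui = u
    r2 = ur * ur + ui * ui
    return [
        (a - r2) * ur - domega * ui + f,
        (a - r2) * ui + domega * ur,
    ]


def response_amplitude(
    a: float,
    stim: StimulusSpec,
    omega0: float,
    z0: complex = 0.001 + 0.0j,
) -> float:
    """Steady-state response amplitude |Z| of a noise-free forced node.

    The forced normal form is integrated in the frame co-rotating with the
    stimulus (an exact change of variables u = z exp(-i w_F t), under which
    |z| = |u|), using an adaptive Runge-Kutta scheme; the amplitude is the
    mean |u| over the final 20% of the run.  Noise is excluded by
    definition of this analysis.

    ``stim.duration`` of 0 selects a horizon long enough for the slowest
    regime (the cubic-dominated resonant response) to equilibrate.
    """
    f = stim.F
    domega = omega0 - stim.omega_f
    duration = stim.duration
    if duration <= 0:
        if a > 1e-12:
            rate = max(a, 3.0 * max(f, 1e-30) ** (2.0 / 3.0))
        elif a < -1e-12:
            rate = abs(a)
        else:
            rate = 3.0 * max(f, 1e-30) ** (2.0 / 3.0)
        duration = max(200.0, 12.0 / rate)
    t_eval = np.linspace(0.8 * duration, duration, 200)
    sol = spi.solve_ivp(
        _rotating_frame_rhs,
        (0.0, duration),
        [z0.real, z0.imag],
        args=(a, domega, f),
        method="RK45",
        rtol=1e-9,
        atol=1e-12,
        t_eval=t_eval,
        max_step=duration / 50.0,
    )
    if not sol.success:
        raise IntegrationError(f"forced-node integration failed: {sol.message}")
    amp = np.hypot(sol.y[0], sol.y[1])
    if not np.all(np.isfinite(amp)):
        raise IntegrationError("forced-node response is non-finite")
    return float(amp.mean())


def power_law_exponent(
    a: float, F_grid: np.ndarray, omega0: float
) -> float:
    """Least-squares slope of log |Z| vs log F at resonance.

    Near the bifurcation (a = 0) the resonant response follows
    |Z| = F^(1/3); deep in the stable-focus regime the response is linear
    in F.  ``F_grid`` must be positive and span at least two decades.
    """
    F_grid = np.asarray(F_grid, dtype=float)
    if np.any(F_grid <= 0):
        raise ParameterError("forcing amplitudes must be positive")
    if F_grid.max() / F_grid.min() < 100.0:
        raise ParameterError("F_grid must span at least two decades")
    amps = [
        response_amplitude(a, StimulusSpec(F=f, omega_f=omega0), omega0)
        for f in F_grid
    ]
    slope, _, _, _, _ = stats.linregress(np.log(F_grid), np.log(amps))
    return float(slope)
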