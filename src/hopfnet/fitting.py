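"""Working-point fitting: (G, a) parameter sweeps, optimal-fit curves and
between-state difference curves.

For every grid point the network is simulated, filtered to the analysis
band, z-scored and summarised exactly as the empirical data (FC matrix,
synchrony, metastability), with repeats averaged to tame the simulation
noise.  The fit criterion is the Euclidean distance between the
strictly-upper-triangle FC vectors of model and data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import compute_fc, fc_distance, phase_locking_stats
from .containers import ConnMatrix, FilterSpec, HopfParams, RoiTimeSeries
from .exceptions import HopfnetError, ShapeError
from .hopf import simulate_network
from .inference import PermutationResult
from .signals import preprocess

__all__ = [
    "FitSurface",
    "OptimalCurve",
    "StateDifference",
    "sweep",
    "optimal_curves",
    "best_match_curve",
    "state_difference_curve",
]

#: Grid of the full-fidelity exploration: G in 0..3 step 0.1, a in
#: -0.5..0.5 step 0.02.  Tests and examples use reduced grids.
DEFAULT_G_GRID = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)
DEFAULT_A_GRID = np.round(np.arange(-0.5, 0.5 + 1e-9, 0.02), 10)


@dataclass
class FitSurface:
    """Per-(G, a) fit summaries: FC distance, synchrony, metastability.

    ``valid`` flags cells whose simulations completed; failed cells hold
    NaN and are skipped by the curve extractors.
    """

    g_values: np.ndarray
    a_values: np.ndarray
    distance: np.ndarray      # (n_G, n_a)
    synchrony: np.ndarray
    metastability: np.ndarray
    valid: np.ndarray
    n_repeats: int = 1


@dataclass
class OptimalCurve:
    """Row/column minima of a fit surface.

    Per G (restricted to G >= g_min): the a of minimal distance; per a:
    the G of minimal distance.  NaN marks rows/columns with no valid cell.
    """

    g_values: np.ndarray
    a_opt: np.ndarray
    d_min_per_g: np.ndarray
    a_values: np.ndarray
    g_opt: np.ndarray
    d_min_per_a: np.ndarray


@dataclass
class StateDifference:
    """Pointwise difference between two optimal curves with a surrogate
    envelope and inclusive p-values per abscissa."""

    abscissa: np.ndarray
    observed: np.ndarray
    surrogates: np.ndarray     # (n_surrogates, n_abscissa)
    p_values: np.ndarray


def sweep(
    fc_emp: ConnMatrix,
    omega: np.ndarray,
    sc: ConnMatrix | np.ndarray,
    *,
    g_values: np.ndarray,
    a_values: np.ndarray,
    tr: float,
    n_volumes: int,
    band: FilterSpec,
    n_repeats: int = 5,
    transient_volumes: int = 20,
    seed: int = 0,
) -> FitSurface:
    """Explore the (G, a) grid against an empirical FC matrix.

    Simulated series match the duration of the empirical recordings and go
    through the identical preprocessing (band-pass + z-score) before FC and
    phase statistics.  Metrics are averaged over ``n_repeats`` noise
    realisations.  A cell whose simulation blows up is marked invalid and
    the sweep continues.
    """
    g_values = np.asarray(g_values, dtype=float)
    a_values = np.asarray(a_values, dtype=float)
    if g_values.size == 0 or a_values.size == 0:
        raise ShapeError("empty grid")
    shape = (g_values.size, a_values.size)
    distance = np.full(shape, np.nan)
    synchrony = np.full(shape, np.nan)
    metastability = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    iu = np.triu_indices(fc_emp.n, k=1)
    emp_upper = fc_emp.values[iu]
    for gi, g in enumerate(g_values):
        for ai, a in enumerate(a_values):
            fc_acc, s_acc, m_acc = [], [], []
            try:
                for rep in range(n_repeats):
                    cell_seed = int(
                        np.random.SeedSequence([seed, gi, ai, rep]).generate_state(1)[0]
                        % (2**31 - 1)
                    )
                    params = HopfParams.for_tr(
                        a=float(a), G=float(g), omega=omega, tr=tr,
                        n_volumes=n_volumes, transient_volumes=transient_volumes,
                        seed=cell_seed,
                    )
                    sim = simulate_network(params, sc)
                    ts = RoiTimeSeries(data=sim.x, tr=tr)
                    clean = preprocess(ts, band)
                    fc_acc.append(compute_fc(clean).values[iu])
                    stats_ = phase_locking_stats(clean, band, preprocessed=True)
                    s_acc.append(stats_.synchrony)
                    m_acc.append(stats_.metastability)
            except HopfnetError:
                continue  # cell stays invalid
            # average the model FC across noise repeats before the distance:
            # the sampling-noise term then shrinks ~1/n_repeats instead of
            # inflating every cell's distance uniformly
            distance[gi, ai] = float(np.linalg.norm(np.mean(fc_acc, axis=0) - emp_upper))
            synchrony[gi, ai] = np.mean(s_acc)
            metastability[gi, ai] = np.mean(m_acc)
            valid[gi, ai] = True
    return FitSurface(
        g_values=g_values, a_values=a_values, distance=distance,
        synchrony=synchrony, metastability=metastability, valid=valid,
        n_repeats=n_repeats,
    )


def _argmin_tiebreak(values: np.ndarray, keys: np.ndarray) -> int:
    """Index of the minimum of ``values``; exact ties resolved by the
    smallest ``keys`` entry."""
    m = np.nanmin(values)
    tied = np.flatnonzero(values == m)
    return int(tied[np.argmin(keys[tied])])


def optimal_curves(surface: FitSurface, g_min: float = 0.2) -> OptimalCurve:
    """Extract per-G and per-a distance minima from a fit surface.

    Ties along a are broken toward the a nearest zero (then the more
    negative of the pair); ties along G toward the smaller G.
    """
    keep = surface.g_values >= g_min - 1e-12
    g_values = surface.g_values[keep]
    dist = surface.distance[keep]
    n_g, n_a = dist.shape
    a_opt = np.full(n_g, np.nan)
    d_min_g = np.full(n_g, np.nan)
    a_keys = np.abs(surface.a_values) + 1e-12 * (surface.a_values > 0)
    for gi in range(n_g):
        row = dist[gi]
        if np.all(np.isnan(row)):
            continue
        idx = _argmin_tiebreak(np.where(np.isnan(row), np.inf, row), a_keys)
        a_opt[gi] = surface.a_values[idx]
        d_min_g[gi] = row[idx]
    g_opt = np.full(n_a, np.nan)
    d_min_a = np.full(n_a, np.nan)
    for ai in range(n_a):
        col = surface.distance[keep][:, ai]
        if np.all(np.isnan(col)):
            continue
        idx = _argmin_tiebreak(np.where(np.isnan(col), np.inf, col), g_values)
        g_opt[ai] = g_values[idx]
        d_min_a[ai] = col[idx]
    return OptimalCurve(
        g_values=g_values, a_opt=a_opt, d_min_per_g=d_min_g,
        a_values=surface.a_values, g_opt=g_opt, d_min_per_a=d_min_a,
    )


def best_match_curve(
    surface: FitSurface, target: float, field: str = "synchrony"
) -> np.ndarray:
    """Per-G bifurcation parameter whose simulated synchrony (or
    metastability) is closest to an empirical target value."""
    values = getattr(surface, field)
    out = np.full(surface.g_values.size, np.nan)
    for gi in range(surface.g_values.size):
        row = values[gi]
        if np.all(np.isnan(row)):
            continue
        out[gi] = surface.a_values[np.nanargmin(np.abs(row - target))]
    return out


def state_difference_curve(
    curve_a: OptimalCurve,
    curve_b: OptimalCurve,
    surrogate_curves: list[tuple[OptimalCurve, OptimalCurve]],
    field: str = "a_opt",
) -> StateDifference:
    """Difference of two optimal curves against a surrogate envelope.

    ``field`` selects what is differenced: the optimal a per G ("a_opt"),
    the minimal distance per G ("d_min_per_g"), or the per-a quantities.
    P-values are inclusive and one-sided in the direction of each observed
    point.
    """
    per_a = field in ("g_opt", "d_min_per_a")
    absc = curve_a.a_values if per_a else curve_a.g_values
    absc_b = curve_b.a_values if per_a else curve_b.g_values
    if absc.shape != absc_b.shape or not np.allclose(absc, absc_b):
        raise ShapeError("curves are defined on different grids")
    observed = getattr(curve_a, field) - getattr(curve_b, field)
    surr = np.stack(
        [getattr(sa, field) - getattr(sb, field) for sa, sb in surrogate_curves]
    )
    n_surr = surr.shape[0]
    p = np.full(observed.shape, np.nan)
    for i, obs in enumerate(observed):
        col = surr[:, i]
        ok = np.isfinite(col)
        if not np.isfinite(obs) or not np.any(ok):
            continue
        if obs >= 0:
            extreme = np.sum(col[ok] >= obs)
        else:
            extreme = np.sum(col[ok] <= obs)
        p[i] = (1.0 + extreme) / (1.0 + np.sum(ok))
    return StateDifference(abscissa=absc, observed=observed, surrogates=surr, p_values=p)
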