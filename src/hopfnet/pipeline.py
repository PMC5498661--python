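"""End-to-end study orchestration.

:func:`run_study` drives the full analysis on a synthetic (or loaded)
two-state cohort: group connectivity metrics with permutation tests, the
Gaussian state classifier, the (G, a) working-point sweep with optimal-fit
curves, effective-connectivity estimation per state, and the forced-node
response analysis.  Every stage writes its artefacts under the output
directory and failures are isolated per stage, so independent stages still
run.  All randomness derives from a single master seed recorded in the run
manifest, making runs replayable.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import jackknife_classify
from .cohort import (
    CohortSpec,
    SyntheticStudy,
    generate_sc,
    generate_two_state_cohort,
    load_study,
    save_study,
)
from .connectivity import (
    compute_fc,
    fc_summary,
    group_average_fc,
    phase_locking_stats,
)
from .containers import FilterSpec
from .connectivity import node_strength
from .ec import ECConfig, compare_ec_groups, estimate_ec, prepare_sc, prescale_by_synchrony
from .fitting import optimal_curves, sweep
from .hopf import estimate_intrinsic_frequencies, power_law_exponent
from .inference import group_scalar_difference, permutation_test
from .signals import preprocess

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "make_fixtures"]


@dataclass
class RunConfig:
    """Configuration of one study run; see :func:`run_study`.

    ``study_dir`` may point to a saved study (manifest.json) to analyse
    user data; otherwise a synthetic cohort is generated from ``cohort``.
    """

    out_dir: str = "hopfnet_run"
    seed: int = 0
    study_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    sc_density: float = 0.3
    band: FilterSpec = field(default_factory=FilterSpec)
    n_surrogates: int = 100
    g_values: list[float] = field(default_factory=lambda: [round(0.5 + 0.5 * i, 2) for i in range(5)])
    a_values: list[float] = field(default_factory=lambda: [round(-0.16 + 0.04 * i, 2) for i in range(5)])
    sweep_repeats: int = 3
    sweep_surrogates: int = 0
    ec: ECConfig = field(default_factory=ECConfig)
    response_a: tuple[float, float] = (0.0, -0.3)
    make_figures: bool = True

    @classmethod
    def small(cls, out_dir: str = "hopfnet_run", seed: int = 0) -> "RunConfig":
        """A desk-scale configuration that completes in about a minute."""
        return cls(
            out_dir=out_dir,
            seed=seed,
            cohort=CohortSpec(n_subjects=4, n_rois=16, n_volumes=200, seed=seed),
            n_surrogates=50,
            sweep_repeats=2,
            ec=ECConfig(max_iter=20, n_repeats=2, n_volumes=200),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from JSON or YAML."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        cohort = CohortSpec(**raw.pop("cohort", {}))
        band = FilterSpec(**raw.pop("band", {}))
        ecfg = ECConfig(**raw.pop("ec", {}))
        return cls(cohort=cohort, band=band, ec=ecfg, **raw)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def run_study(config: RunConfig) -> dict:
    """Run the full two-state analysis; returns the summary dictionary.

    Artefacts written under ``config.out_dir``: the study data, per-stage
    JSON results, figures (when ``make_figures``) and ``summary.json`` plus
    a ``manifest.json`` with seeds and versions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ["sc", "perm", "classify", "sweep", "ec", "surrogate"], ss.spawn(6)
        )
    }
    summary: dict = {"config_seed": config.seed, "stages": {}, "errors": {}}

    # --- data ---------------------------------------------------------
    if config.study_dir is not None:
        study = load_study(config.study_dir)
    else:
        sc = generate_sc(config.cohort.n_rois, config.sc_density, seeds["sc"])
        study = generate_two_state_cohort(config.cohort, sc)
    save_study(study, out / "study")
    states = study.states
    st_a, st_b = states[0], states[1]  # e.g. awake, sleep (sorted)

    preprocessed = {
        id(ts.data): preprocess(ts, config.band) for ts in study.cohort
    }

    def clean(ts):
        key = id(ts.data)
        if key not in preprocessed:
            preprocessed[key] = preprocess(ts, config.band)
        return preprocessed[key]

    # --- stage: connectivity metrics + permutation tests --------------
    try:
        metrics: dict = {}
        group_fc = {}
        for state in states:
            fcs = [compute_fc(clean(ts)) for ts in study.recordings(state)]
            group_fc[state] = group_average_fc(fcs)
            mean, sd = fc_summary(group_fc[state])
            stats_ = [phase_locking_stats(clean(ts), config.band, preprocessed=True)
                      for ts in study.recordings(state)]
            metrics[state] = {
                "fc_mean": mean,
                "fc_sd": sd,
                "synchrony": float(np.mean([s.synchrony for s in stats_])),
                "metastability": float(np.mean([s.metastability for s in stats_])),
            }

        def metric_stat(fn):
            return permutation_test(
                group_scalar_difference(fn, st_a, st_b), study.cohort,
                n_surrogates=config.n_surrogates, seed=seeds["perm"], sided="one",
            )

        tests = {
            "fc_mean": metric_stat(lambda ts: fc_summary(compute_fc(clean(ts)))[0]),
            "synchrony": metric_stat(
                lambda ts: phase_locking_stats(clean(ts), config.band, preprocessed=True).synchrony
            ),
            "metastability": metric_stat(
                lambda ts: phase_locking_stats(clean(ts), config.band, preprocessed=True).metastability
            ),
        }
        metrics["tests"] = {
            name: {"observed": r.observed, "p": r.p_value, "sided": r.sided}
            for name, r in tests.items()
        }
        summary["stages"]["metrics"] = metrics
        _write_json(out / "metrics.json", metrics)
        if config.make_figures:
            _plot_metric_tests(tests, out / "metrics_permutation.png")
    except Exception:
        summary["errors"]["metrics"] = traceback.format_exc()
        group_fc = {}

    # --- stage: Gaussian classifier -----------------------------------
    try:
        report = jackknife_classify([clean(ts) for ts in study.cohort])
        cls_payload = {
            "per_state_accuracy": report.per_state_accuracy,
            "chance_threshold": report.chance_threshold,
            "n_subjects": report.n_subjects,
            "ties": report.ties,
        }
        summary["stages"]["classifier"] = cls_payload
        _write_json(out / "classifier.json", cls_payload)
        if config.make_figures:
            _plot_classifier(report, out / "classifier.png")
    except Exception:
        summary["errors"]["classifier"] = traceback.format_exc()

    # --- stage: working-point sweep -----------------------------------
    try:
        if not group_fc:
            raise RuntimeError("sweep requires the metrics stage")
        curves = {}
        for state in states:
            filtered = [clean(ts) for ts in study.recordings(state)]
            omega = estimate_intrinsic_frequencies(filtered, config.band)
            surf = sweep(
                group_fc[state], omega, study.sc,
                g_values=np.asarray(config.g_values),
                a_values=np.asarray(config.a_values),
                tr=config.cohort.tr, n_volumes=config.cohort.n_volumes,
                band=config.band, n_repeats=config.sweep_repeats,
                seed=seeds["sweep"],
            )
            curves[state] = optimal_curves(surf, g_min=min(config.g_values))
            np.savez(
                out / f"sweep_{state}.npz",
                g_values=surf.g_values, a_values=surf.a_values,
                distance=surf.distance, synchrony=surf.synchrony,
                metastability=surf.metastability,
            )
            if config.make_figures:
                _plot_surface(surf, state, out / f"sweep_{state}.png")
        sweep_payload = {
            state: {
                "g_values": curves[state].g_values,
                "a_opt": curves[state].a_opt,
                "d_min": curves[state].d_min_per_g,
            }
            for state in states
        }
        sweep_payload["a_opt_difference"] = (
            curves[st_a].a_opt - curves[st_b].a_opt
        )
        summary["stages"]["sweep"] = sweep_payload
        _write_json(out / "sweep_curves.json", sweep_payload)
    except Exception:
        summary["errors"]["sweep"] = traceback.format_exc()

    # --- stage: effective connectivity --------------------------------
    try:
        if not group_fc:
            raise RuntimeError("EC requires the metrics stage")
        prepared = prepare_sc(study.sc, study.homologous_pairs)
        ec_results = {}
        for state in states:
            filtered = [clean(ts) for ts in study.recordings(state)]
            omega = estimate_intrinsic_frequencies(filtered, config.band)
            target_sync = summary["stages"]["metrics"][state]["synchrony"]
            scaled, rounds = prescale_by_synchrony(
                prepared, target_sync, omega, config.ec, seed=seeds["ec"]
            )
            trace = estimate_ec(
                scaled, group_fc[state], omega, config.ec, seed=seeds["ec"]
            )
            ec_results[state] = trace
            np.save(out / f"ec_{state}.npy", trace.ec.values)
            _trace_csv(trace, out / f"ec_trace_{state}.csv")
        comparison = compare_ec_groups(ec_results[st_a].ec, ec_results[st_b].ec)
        ec_payload = {
            "mean_strength": {
                state: float(node_strength(ec_results[state].ec).mean())
                for state in states
            },
            "mean_difference": comparison.mean_difference,
            "n_nodes_higher": comparison.n_higher,
            "final_distance": {
                state: float(ec_results[state].distances[-1]) for state in states
            },
        }
        summary["stages"]["ec"] = ec_payload
        _write_json(out / "ec_summary.json", ec_payload)
        if config.make_figures:
            _plot_ec_traces(ec_results, out / "ec_traces.png")
    except Exception:
        summary["errors"]["ec"] = traceback.format_exc()

    # --- stage: stimulus response -------------------------------------
    try:
        f_grid = np.logspace(-4, -2, 7)
        response = {
            f"slope_a={a}": power_law_exponent(a, f_grid, omega0=1.0)
            for a in config.response_a
        }
        summary["stages"]["response"] = response
        _write_json(out / "response.json", response)
    except Exception:
        summary["errors"]["response"] = traceback.format_exc()

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "config": _jsonable(
            {**asdict(config), "cohort": asdict(config.cohort),
             "band": asdict(config.band), "ec": asdict(config.ec)}
        ),
    }
    _write_json(out / "manifest.json", manifest)
    _write_json(out / "summary.json", summary)
    return summary


def make_fixtures(out_dir: str | Path, seed: int = 0) -> SyntheticStudy:
    """Write a miniature study (6 subjects, 20 ROIs, 300 volumes) used by
    the test suite and the examples."""
    spec = CohortSpec(n_subjects=6, n_rois=20, n_volumes=300, seed=seed)
    sc = generate_sc(spec.n_rois, density=0.35, seed=seed)
    study = generate_two_state_cohort(spec, sc)
    save_study(study, out_dir)
    return study


def _trace_csv(trace, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "iteration": trace.accepted_iterations,
            "distance": trace.distances,
            "fc_correlation": trace.correlations,
        }
    ).to_csv(path, index=False)


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _plot_metric_tests(tests, path: Path) -> None:
    plt = _mpl()
    fig, axes = plt.subplots(1, len(tests), figsize=(4 * len(tests), 3))
    for ax, (name, res) in zip(np.atleast_1d(axes), tests.items()):
        ax.hist(res.surrogates, bins=20, color="k", alpha=0.7)
        ax.axvline(res.observed, color="g", lw=2)
        ax.set_title(f"{name}: p={res.p_value:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_classifier(report, path: Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 3))
    states = list(report.per_state_accuracy)
    ax.bar(states, [report.per_state_accuracy[s] for s in states], color=["purple", "gold"])
    if np.isfinite(report.chance_threshold):
        ax.axhline(report.chance_threshold, ls="--", color="k", label="chance threshold")
        ax.legend()
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_surface(surf, state: str, path: Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        surf.distance, origin="lower", aspect="auto",
        extent=[surf.a_values[0], surf.a_values[-1], surf.g_values[0], surf.g_values[-1]],
    )
    fig.colorbar(im, ax=ax, label="FC distance")
    ax.set_xlabel("a")
    ax.set_ylabel("G")
    ax.set_title(f"fit surface: {state}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_ec_traces(ec_results, path: Path) -> None:
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for state, trace in ec_results.items():
        axes[0].plot(trace.accepted_iterations, trace.distances, label=state)
        axes[1].plot(trace.accepted_iterations, trace.correlations, label=state)
    axes[0].set_ylabel("FC distance")
    axes[1].set_ylabel("FC correlation")
    for ax in axes:
        ax.set_xlabel("iteration")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
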