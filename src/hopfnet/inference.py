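"""Surrogate construction and permutation inference.

The design is paired: every subject contributes one recording per state.
Null datasets are built by flipping each subject's two state labels with
probability 1/2, which preserves pairing and group sizes while destroying
any systematic state difference.  P-values use the inclusive (add-one)
convention, so the smallest attainable value with ``n`` surrogates is
1 / (n + 1) — 0.0099 for the default 100 surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .containers import RoiTimeSeries
from .exceptions import DesignError, ShapeError

__all__ = [
    "ShuffledCohort",
    "PermutationResult",
    "shuffle_states",
    "permutation_test",
    "count_nodes_higher",
    "group_scalar_difference",
]


@dataclass
class ShuffledCohort:
    """A relabelled view of a paired cohort.

    ``assignment`` maps each subject to True when its two state labels were
    swapped.  Recordings share the original data arrays; only the state
    labels differ.
    """

    assignment: dict[str, bool]
    recordings: list[RoiTimeSeries]


@dataclass
class PermutationResult:
    """Observed statistic, surrogate null distribution and inclusive p."""

    observed: float
    surrogates: np.ndarray
    p_value: float
    sided: str
    seed: int


def _as_recordings(cohort) -> list[RoiTimeSeries]:
    if hasattr(cohort, "cohort"):  # SyntheticStudy
        return list(cohort.cohort)
    return list(cohort)


def _paired_by_subject(recordings: Sequence[RoiTimeSeries]):
    states = sorted({ts.state for ts in recordings})
    if len(states) != 2:
        raise DesignError(f"expected exactly two states, got {states}")
    by_subject: dict[str, dict[str, RoiTimeSeries]] = {}
    for ts in recordings:
        by_subject.setdefault(ts.subject, {})[ts.state] = ts
    for subject, pair in by_subject.items():
        if set(pair) != set(states):
            raise DesignError(f"subject {subject!r} lacks a recording in both states")
    return states, by_subject


def shuffle_states(cohort, seed: int) -> ShuffledCohort:
    """Swap each subject's two state labels with independent probability 1/2.

    Recordings never mix across subjects; group sizes are unchanged by
    construction.
    """
    recordings = _as_recordings(cohort)
    states, by_subject = _paired_by_subject(recordings)
    rng = np.random.default_rng(seed)
    subjects = sorted(by_subject)
    flips = rng.random(len(subjects)) < 0.5
    assignment = dict(zip(subjects, (bool(f) for f in flips)))
    other = {states[0]: states[1], states[1]: states[0]}
    shuffled = [
        ts.with_state(other[ts.state]) if assignment[ts.subject] else ts
        for ts in recordings
    ]
    return ShuffledCohort(assignment=assignment, recordings=shuffled)


def permutation_test(
    stat_fn: Callable[[list[RoiTimeSeries]], float],
    cohort,
    n_surrogates: int = 100,
    seed: int = 0,
    sided: str = "one",
) -> PermutationResult:
    """Permutation test of a group statistic against state-shuffled nulls.

    Parameters
    ----------
    stat_fn : callable
        Maps a list of labelled recordings to a scalar (typically a signed
        awake-minus-sleep difference).
    sided : {"one", "two", "greater", "less"}
        "one" tests in the direction of the observed sign; "two" compares
        absolute values.

    The p-value is inclusive: p = (1 + #{surrogates at least as extreme}) /
    (1 + n_surrogates), so p is never 0.
    """
    if n_surrogates < 1:
        raise ShapeError("n_surrogates must be >= 1")
    recordings = _as_recordings(cohort)
    observed = float(stat_fn(recordings))
    child_seeds = np.random.SeedSequence(seed).generate_state(n_surrogates) % (2**31)
    surrogates = np.empty(n_surrogates)
    for k, s in enumerate(child_seeds):
        shuffled = shuffle_states(recordings, int(s))
        try:
            surrogates[k] = float(stat_fn(shuffled.recordings))
        except Exception as exc:  # surface which shuffle failed
            raise RuntimeError(f"stat_fn failed on surrogate {k}") from exc

    if sided == "two":
        extreme = np.sum(np.abs(surrogates) >= abs(observed))
    elif sided == "greater" or (sided == "one" and observed >= 0):
        extreme = np.sum(surrogates >= observed)
    elif sided == "less" or sided == "one":
        extreme = np.sum(surrogates <= observed)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = (1.0 + float(extreme)) / (1.0 + n_surrogates)
    return PermutationResult(observed, surrogates, p, sided, seed)


def count_nodes_higher(ns_a: np.ndarray, ns_b: np.ndarray) -> int:
    """Number of nodes with strictly higher strength in ``ns_a`` than ``ns_b``."""
    ns_a = np.asarray(ns_a, dtype=float)
    ns_b = np.asarray(ns_b, dtype=float)
    if ns_a.shape != ns_b.shape:
        raise ShapeError(f"length mismatch: {ns_a.shape} vs {ns_b.shape}")
    return int(np.sum(ns_a > ns_b))


def group_scalar_difference(
    metric: Callable[[RoiTimeSeries], float],
    state_a: str,
    state_b: str,
) -> Callable[[list[RoiTimeSeries]], float]:
    """Build a stat_fn: mean of ``metric`` over state_a minus over state_b.

    The per-recording metric is cached by object identity, so label-only
    shuffles (which share data arrays) never recompute it — this makes
    permutation tests with expensive metrics cheap.
    """
    cache: dict[int, float] = {}

    def stat(recordings: Iterable[RoiTimeSeries]) -> float:
        groups: dict[str, list[float]] = {state_a: [], state_b: []}
        for ts in recordings:
            if ts.state not in groups:
                continue
            key = id(ts.data)
            if key not in cache:
                cache[key] = float(metric(ts))
            groups[ts.state].append(cache[key])
        if not groups[state_a] or not groups[state_b]:
            raise DesignError(f"states {state_a!r}/{state_b!r} not found in cohort")
        return float(np.mean(groups[state_a]) - np.mean(groups[state_b]))

    return stat
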