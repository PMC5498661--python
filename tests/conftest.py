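"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hopfnet import CohortSpec, FilterSpec, generate_sc, generate_two_state_cohort


@pytest.fixture(scope="session")
def band() -> FilterSpec:
    return FilterSpec(0.04, 0.07, 6)


@pytest.fixture(scope="session")
def small_study():
    """Miniature two-state study (6 subjects, 20 ROIs, 300 volumes) at the
    default awake/sleep working points."""
    spec = CohortSpec(n_subjects=6, n_rois=20, n_volumes=300, seed=42)
    sc = generate_sc(spec.n_rois, density=0.35, seed=42)
    return generate_two_state_cohort(spec, sc)


@pytest.fixture(scope="session")
def null_study():
    """Cohort whose two states share the same working point: any group
    difference is pure noise."""
    params = {"awake": (-0.07, 1.5), "sleep": (-0.07, 1.5)}
    spec = CohortSpec(
        n_subjects=6, n_rois=12, n_volumes=200, state_params=params, seed=7
    )
    sc = generate_sc(spec.n_rois, density=0.4, seed=7)
    return generate_two_state_cohort(spec, sc)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(1234)
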