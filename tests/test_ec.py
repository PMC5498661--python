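"""SC preparation, synchrony pre-scaling and the EC gradient descent."""

import numpy as np
import pytest

from hopfnet import (
    ConnMatrix,
    ECConfig,
    FilterSpec,
    compute_fc,
    estimate_ec,
    generate_sc,
    prepare_sc,
    prescale_by_synchrony,
    preprocess,
    validate_roundtrip,
)
from hopfnet.cohort import default_homologous_pairs
from hopfnet.connectivity import node_strength, phase_locking_stats
from hopfnet.containers import RoiTimeSeries
from hopfnet.ec import MACHINE_EPS, _simulate_fc, compare_ec_groups
from hopfnet.exceptions import DegenerateSignalError, ShapeError


@pytest.fixture(scope="module")
def prepared_sc():
    sc = generate_sc(12, density=0.4, seed=31)
    return prepare_sc(sc, default_homologous_pairs(12))


@pytest.fixture(scope="module")
def omega12():
    rng = np.random.default_rng(31)
    return 2 * np.pi * rng.uniform(0.04, 0.07, 12)


def _fast_cfg(**kw):
    defaults = dict(max_iter=8, n_repeats=2, n_volumes=150)
    defaults.update(kw)
    return ECConfig(**defaults)


class TestPrepareSC:
    def test_maximum_is_exactly_point_two(self):
        sc = generate_sc(10, density=0.5, seed=1)
        prepared = prepare_sc(sc, [])
        assert prepared.values.max() == 0.2

    def test_existing_homologous_links_untouched(self):
        values = np.zeros((4, 4))
        values[0, 2] = values[2, 0] = 5.0  # homologous pair (0, 2), present
        values[0, 1] = values[1, 0] = 1.0
        sc = ConnMatrix(values=values, role="SC")
        prepared = prepare_sc(sc, default_homologous_pairs(4))
        assert prepared.values[0, 2] == 0.2  # only rescaled
        # missing homologous pair (1, 3) receives the epsilon
        assert prepared.values[1, 3] == MACHINE_EPS
        assert prepared.values[3, 1] == MACHINE_EPS

    def test_non_homologous_zeros_preserved(self):
        values = np.zeros((6, 6))
        values[0, 3] = values[3, 0] = 2.0
        sc = ConnMatrix(values=values, role="SC")
        prepared = prepare_sc(sc, [(0, 3)])
        off_pairs = [(0, 1), (0, 2), (1, 2), (2, 4)]
        for i, j in off_pairs:
            assert prepared.values[i, j] == 0.0

    def test_all_zero_matrix_rejected(self):
        sc = ConnMatrix(values=np.zeros((4, 4)), role="SC")
        with pytest.raises(DegenerateSignalError):
            prepare_sc(sc, [])


class TestPrescale:
    def test_target_already_close_means_no_scaling(self, prepared_sc, omega12):
        cfg = _fast_cfg()
        _, sync = _simulate_fc(prepared_sc.values, omega12, cfg, 5, want_sync=True)
        scaled, rounds = prescale_by_synchrony(prepared_sc, sync, omega12, cfg, seed=5)
        assert rounds == 0
        assert np.array_equal(scaled.values, prepared_sc.values)

    def test_higher_target_scales_weights_up(self, prepared_sc, omega12):
        cfg = _fast_cfg(prescale_max_rounds=1, prescale_tol=0.01)
        with pytest.warns(UserWarning):
            scaled, _ = prescale_by_synchrony(
                prepared_sc, 0.95, omega12, cfg, seed=5
            )
        assert scaled.values.max() > prepared_sc.values.max()

    def test_invalid_target_rejected(self, prepared_sc, omega12):
        with pytest.raises(ShapeError):
            prescale_by_synchrony(prepared_sc, 1.5, omega12, _fast_cfg(), seed=0)


@pytest.fixture(scope="module")
def ec_run(prepared_sc, omega12):
    """One short descent against the FC of an independent simulation."""
    cfg = _fast_cfg(max_iter=12)
    fc_target, _ = _simulate_fc(prepared_sc.values * 1.3, omega12, cfg, 99)
    fc_target = ConnMatrix(values=np.clip((fc_target + fc_target.T) / 2, -1, 1), role="FC")
    trace = estimate_ec(prepared_sc, fc_target, omega12, cfg, seed=7)
    return prepared_sc, fc_target, trace


class TestEstimateEC:
    def test_zero_pattern_preserved(self, ec_run):
        prepared, _, trace = ec_run
        assert np.array_equal(trace.ec.values == 0.0, prepared.values == 0.0)

    def test_accepted_distances_monotone_non_increasing(self, ec_run):
        _, _, trace = ec_run
        assert np.all(np.diff(trace.distances) <= 0)
        assert trace.distances[-1] <= trace.distances[0]

    def test_weights_bounded_below_by_epsilon_floor(self, ec_run):
        prepared, _, trace = ec_run
        on_links = trace.ec.values[prepared.values > 0]
        assert np.all(on_links >= MACHINE_EPS)

    def test_zero_iterations_return_prepared_matrix(self, prepared_sc, omega12):
        cfg = _fast_cfg(max_iter=0)
        fc_target, _ = _simulate_fc(prepared_sc.values, omega12, cfg, 1)
        fc_target = ConnMatrix(values=np.clip((fc_target + fc_target.T) / 2, -1, 1), role="FC")
        trace = estimate_ec(prepared_sc, fc_target, omega12, cfg, seed=2)
        assert np.array_equal(trace.ec.values, prepared_sc.values)
        corr, t1, t2 = validate_roundtrip(prepared_sc, fc_target, omega12, cfg, seed=2)
        assert corr == pytest.approx(1.0)


class TestCompareECGroups:
    def test_global_scaling_detected(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        ec_a = ConnMatrix(values=v, role="EC")
        ec_b = ConnMatrix(values=0.8 * v, role="EC")
        result = compare_ec_groups(ec_a, ec_b)
        assert result.n_higher == 8
        assert result.mean_difference == pytest.approx(
            0.2 * node_strength(ec_a).mean()
        )

    def test_identical_inputs_no_difference(self):
        v = np.ones((5, 5)) - np.eye(5)
        ec = ConnMatrix(values=v, role="EC")
        result = compare_ec_groups(ec, ec)
        assert result.n_higher == 0
        assert result.mean_difference == 0.0

    def test_surrogate_p_values_inclusive(self):
        v = np.ones((4, 4)) - np.eye(4)
        ec_a = ConnMatrix(values=2 * v, role="EC")
        ec_b = ConnMatrix(values=v, role="EC")
        surr = [(ec_b, ec_b)] * 9  # null pairs: zero difference
        result = compare_ec_groups(ec_a, ec_b, surrogate_pairs=surr)
        assert result.p_mean == pytest.approx(1.0 / 10.0)
        assert result.p_count == pytest.approx(1.0 / 10.0)
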