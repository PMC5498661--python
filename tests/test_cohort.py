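"""Synthetic structural matrices and two-state cohorts."""

import numpy as np
import pytest

from hopfnet import (
    CohortSpec,
    FilterSpec,
    compute_fc,
    fc_summary,
    generate_sc,
    generate_two_state_cohort,
    group_average_fc,
    load_study,
    preprocess,
    save_study,
)
from hopfnet.cohort import default_homologous_pairs
from hopfnet.exceptions import ParameterError, ShapeError


class TestGenerateSC:
    def test_full_density_links_every_pair(self):
        sc = generate_sc(4, density=1.0, seed=1)
        iu = np.triu_indices(4, k=1)
        assert np.all(sc.values[iu] > 0)

    def test_deterministic_for_fixed_seed(self):
        a = generate_sc(30, density=0.4, seed=7)
        b = generate_sc(30, density=0.4, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_density_is_respected(self):
        sc = generate_sc(90, density=0.3, seed=3)
        iu = np.triu_indices(90, k=1)
        fraction = np.mean(sc.values[iu] > 0)
        assert abs(fraction - 0.3) <= 0.05

    def test_cross_hemisphere_links_sparser(self):
        sc = generate_sc(60, density=0.3, seed=5)
        half = 30
        within = sc.values[:half, :half][np.triu_indices(half, k=1)]
        cross = sc.values[:half, half:]
        assert np.mean(cross > 0) < np.mean(within > 0)

    def test_invalid_density(self):
        with pytest.raises(ParameterError):
            generate_sc(10, density=0.0, seed=0)
        with pytest.raises(ParameterError):
            generate_sc(10, density=1.5, seed=0)

    def test_structure_invariants(self):
        sc = generate_sc(20, density=0.5, seed=2)
        assert np.allclose(sc.values, sc.values.T)
        assert np.all(np.diag(sc.values) == 0)
        assert np.all(sc.values >= 0)


class TestCohortGeneration:
    def test_recording_count_and_shape(self, small_study):
        assert len(small_study.cohort) == 12  # 6 subjects x 2 states
        for ts in small_study.cohort:
            assert ts.data.shape == (20, 300)
            assert ts.tr == 2.08
        subjects = {ts.subject for ts in small_study.cohort}
        assert len(subjects) == 6
        for s in subjects:
            states = sorted(ts.state for ts in small_study.cohort if ts.subject == s)
            assert states == ["awake", "sleep"]

    def test_regeneration_is_bit_identical(self):
        spec = CohortSpec(n_subjects=2, n_rois=8, n_volumes=80, seed=11)
        sc = generate_sc(8, density=0.5, seed=11)
        a = generate_two_state_cohort(spec, sc)
        b = generate_two_state_cohort(spec, sc)
        for ta, tb in zip(a.cohort, b.cohort):
            assert np.array_equal(ta.data, tb.data)

    def test_dimension_mismatch_rejected(self):
        spec = CohortSpec(n_subjects=2, n_rois=8, n_volumes=80, seed=0)
        with pytest.raises(ShapeError):
            generate_two_state_cohort(spec, generate_sc(10, 0.5, 0))

    def test_awake_state_has_higher_group_fc(self, small_study, band):
        means = {}
        for state in ("awake", "sleep"):
            fcs = [
                compute_fc(preprocess(ts, band))
                for ts in small_study.recordings(state)
            ]
            means[state] = fc_summary(group_average_fc(fcs))[0]
        assert means["awake"] > means["sleep"]

    def test_homologous_pairs_are_mirror_indices(self):
        assert default_homologous_pairs(6) == [(0, 3), (1, 4), (2, 5)]
        assert len(default_homologous_pairs(90)) == 45

    def test_ground_truth_matches_spec(self, small_study):
        gt = small_study.ground_truth
        assert gt["awake"].a > gt["sleep"].a
        assert gt["awake"].G > gt["sleep"].G
        omega = gt["awake"].omega
        assert np.all(omega >= 2 * np.pi * 0.04 - 1e-9)
        assert np.all(omega <= 2 * np.pi * 0.07 + 1e-9)


class TestStudyIO:
    def test_save_load_roundtrip(self, tmp_path):
        spec = CohortSpec(n_subjects=2, n_rois=6, n_volumes=80, seed=4)
        study = generate_two_state_cohort(spec, generate_sc(6, 0.6, 4))
        save_study(study, tmp_path / "study")
        loaded = load_study(tmp_path / "study")
        assert len(loaded.cohort) == len(study.cohort)
        for a, b in zip(study.cohort, loaded.cohort):
            assert a.subject == b.subject and a.state == b.state
            assert np.array_equal(a.data, b.data)
        assert np.array_equal(loaded.sc.values, study.sc.values)
        assert loaded.homologous_pairs == study.homologous_pairs
        # text copy of the SC is written alongside the binary one
        sc_txt = np.loadtxt(tmp_path / "study" / "sc.txt")
        assert np.allclose(sc_txt, study.sc.values)


class TestMatrixIO:
    def test_conn_matrix_text_roundtrip(self, tmp_path):
        from hopfnet import read_conn_matrix, write_conn_matrix

        sc = generate_sc(8, density=0.5, seed=2)
        write_conn_matrix(tmp_path / "sc.txt", sc)
        back = read_conn_matrix(tmp_path / "sc.txt")
        assert back.role == "SC"
        assert np.allclose(back.values, sc.values)

    def test_timeseries_text_roundtrip(self, tmp_path):
        from hopfnet import read_timeseries, write_timeseries
        from hopfnet.containers import RoiTimeSeries

        ts = RoiTimeSeries(
            data=np.random.default_rng(0).normal(size=(3, 40)),
            tr=2.08, subject="sub01", state="awake",
        )
        write_timeseries(tmp_path / "ts.txt", ts)
        back = read_timeseries(tmp_path / "ts.txt")
        assert back.subject == "sub01" and back.state == "awake"
        assert back.tr == 2.08
        assert np.allclose(back.data, ts.data)
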