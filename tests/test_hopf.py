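"""Hopf normal form, coupled network simulation and stimulus response."""

import numpy as np
import pytest

from hopfnet import (
    FilterSpec,
    HopfParams,
    RoiTimeSeries,
    StimulusSpec,
    compute_fc,
    estimate_intrinsic_frequencies,
    response_amplitude,
    simulate_network,
    simulate_node,
)
from hopfnet.connectivity import phase_locking_stats
from hopfnet.exceptions import DegenerateSpectrumError, ParameterError, ShapeError
from hopfnet.signals import preprocess


def _node_params(a, beta=0.0, dt=0.005, t_end=2000.0, omega=0.35, seed=0):
    n_steps = int(t_end / dt)
    return HopfParams(
        a=a, G=0.0, omega=np.array([omega]), beta=beta, dt=dt,
        n_steps=n_steps, downsample=1, transient_steps=0, seed=seed,
    )


class TestSingleNode:
    def test_subcritical_node_decays_to_fixed_point(self):
        out = simulate_node(_node_params(a=-0.3, t_end=600.0))
        assert np.abs(out.z[-1]) < 1e-4

    def test_supercritical_amplitude_is_sqrt_a(self):
        out = simulate_node(_node_params(a=0.25))
        tail = np.abs(out.z[-2000:])
        assert tail.mean() == pytest.approx(0.5, abs=1e-3)

    def test_limit_cycle_frequency_matches_omega(self):
        omega = 0.35
        params = _node_params(a=0.25, omega=omega, t_end=4000.0, dt=0.01)
        out = simulate_node(params)
        x = out.z.real[-200_000:]
        freqs = np.fft.rfftfreq(x.size, d=params.dt)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x - x.mean())))]
        assert peak == pytest.approx(omega / (2 * np.pi), rel=0.02)


class TestNetwork:
    def test_identical_seed_bit_identical_output(self):
        omega = 2 * np.pi * np.linspace(0.04, 0.07, 10)
        params = HopfParams.for_tr(a=-0.05, G=1.0, omega=omega, tr=2.08,
                                   n_volumes=50, seed=9)
        C = np.full((10, 10), 0.1) - 0.1 * np.eye(10)
        a = simulate_network(params, C)
        b = simulate_network(params, C)
        assert np.array_equal(a.x, b.x)

    def test_uncoupled_nodes_are_independent(self):
        rng = np.random.default_rng(0)
        omega = 2 * np.pi * rng.uniform(0.04, 0.07, 20)
        params = HopfParams.for_tr(a=-0.05, G=0.0, omega=omega, tr=2.08,
                                   n_volumes=1000, seed=3)
        sim = simulate_network(params, np.zeros((20, 20)))
        fc = compute_fc(RoiTimeSeries(data=sim.x, tr=2.08))
        off = np.abs(fc.upper_triangle())
        assert off.mean() < 0.1

    def test_synchrony_increases_with_coupling(self, band):
        rng = np.random.default_rng(1)
        omega = 2 * np.pi * rng.uniform(0.04, 0.07, 20)
        C = np.abs(rng.normal(size=(20, 20)))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 0.0)
        C *= 0.2 / C.max()
        sync = []
        for g in (0.0, 1.0, 2.0):
            vals = []
            for seed in range(10):
                params = HopfParams.for_tr(a=-0.02, G=g, omega=omega, tr=2.08,
                                           n_volumes=300, seed=100 + seed)
                sim = simulate_network(params, C)
                ts = RoiTimeSeries(data=sim.x, tr=2.08)
                vals.append(phase_locking_stats(ts, band).synchrony)
            sync.append(np.mean(vals))
        assert sync[0] < sync[1] < sync[2]

    def test_strong_diffusive_coupling_synchronises_pair(self):
        # same intrinsic frequency, no noise: diffusive coupling contracts
        # the difference between the two nodes toward zero
        omega = np.array([0.3, 0.3])
        C = np.array([[0.0, 0.2], [0.2, 0.0]])
        params = HopfParams(a=0.1, G=5.0, omega=omega, beta=0.0, dt=0.01,
                            n_steps=100_000, downsample=10, transient_steps=0, seed=4)
        sim = simulate_network(params, C)
        diff = np.abs(sim.x[0, -100:] - sim.x[1, -100:])
        assert diff.max() < 1e-6

    def test_dimension_mismatch(self):
        params = HopfParams.for_tr(a=-0.05, G=1.0, omega=np.ones(5), tr=2.08,
                                   n_volumes=50, seed=0)
        with pytest.raises(ShapeError):
            simulate_network(params, np.zeros((4, 4)))


class TestIntrinsicFrequencies:
    def _tone(self, freq, n_rois=3, t=800, tr=2.08):
        time = np.arange(t) * tr
        data = np.vstack([np.cos(2 * np.pi * freq * time + k) for k in range(n_rois)])
        return RoiTimeSeries(data=data, tr=tr)

    def test_pure_tone_recovered(self, band):
        omega = estimate_intrinsic_frequencies([self._tone(0.05)], band)
        df = 1.0 / (800 * 2.08)
        assert np.allclose(omega / (2 * np.pi), 0.05, atol=df)

    def test_subject_average(self, band):
        omega = estimate_intrinsic_frequencies(
            [self._tone(0.041), self._tone(0.061)], band
        )
        assert np.allclose(omega / (2 * np.pi), 0.051, atol=0.002)

    def test_output_clipped_to_band(self, band, rng):
        ts = RoiTimeSeries(data=rng.normal(size=(4, 400)), tr=2.08)
        clean = preprocess(ts, band)
        omega = estimate_intrinsic_frequencies([clean], band)
        assert np.all(omega >= 2 * np.pi * band.low - 1e-12)
        assert np.all(omega <= 2 * np.pi * band.high + 1e-12)

    def test_flat_spectrum_rejected(self, band):
        ts = RoiTimeSeries(data=np.zeros((2, 200)) + 1e-30, tr=2.08)
        with pytest.raises(DegenerateSpectrumError):
            estimate_intrinsic_frequencies([ts], band)


class TestStimulusResponse:
    def test_linear_regime_amplitude(self):
        amp = response_amplitude(-0.3, StimulusSpec(F=1e-3, omega_f=1.0), omega0=1.0)
        assert amp == pytest.approx(1e-3 / 0.3, rel=0.05)

    def test_resonance_beats_off_resonance(self):
        on = response_amplitude(-0.2, StimulusSpec(F=1e-2, omega_f=1.0), omega0=1.0)
        off = response_amplitude(-0.2, StimulusSpec(F=1e-2, omega_f=2.0), omega0=1.0)
        assert on > off

    def test_f_grid_validation(self):
        from hopfnet import power_law_exponent

        with pytest.raises(ParameterError):
            power_law_exponent(0.0, np.array([1e-3, 2e-3]), 1.0)
        with pytest.raises(ParameterError):
            power_law_exponent(0.0, np.array([-1e-3, 1e-1]), 1.0)
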