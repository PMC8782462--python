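"""Unit and property tests for the transcription/splicing simulator."""

import math

import numpy as np
import pytest

from introflow import (
    GeneKinetics,
    SimulationGrid,
    TFWaveformParams,
    ensemble_benchmark,
    sample_gene_kinetics,
    simulate_ode,
    simulate_tau_leap,
    steady_state,
    tf_waveform,
    thin_detection,
)
from introflow.simulate import _analysis_window, detection_sweep


class TestWaveform:
    def test_basal_peak_and_midpoint(self):
        wf = TFWaveformParams(a_basal=0.06, a_max=0.5, period=5.5)
        assert tf_waveform(wf, 0.0) == pytest.approx(0.06)
        assert tf_waveform(wf, wf.period / 2) == pytest.approx(0.5)
        assert tf_waveform(wf, wf.period / 4) == pytest.approx((0.06 + 0.5) / 2)

    def test_noise_requires_rng_and_clips_at_zero(self, rng):
        wf = TFWaveformParams(a_basal=0.0, a_max=0.01, sigma=5.0, noise_enabled=True)
        with pytest.raises(ValueError):
            tf_waveform(wf, 1.0)
        values = tf_waveform(wf, np.zeros(500), rng=rng)
        assert np.all(values >= 0.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TFWaveformParams(a_basal=0.5, a_max=0.06)
        with pytest.raises(ValueError):
            TFWaveformParams(period=0.0)
        with pytest.raises(ValueError):
            tf_waveform(TFWaveformParams(), -1.0)


class TestKinetics:
    def test_derived_rates(self, rng):
        k = sample_gene_kinetics(rng, half_life=100.0)
        assert k.gamma == pytest.approx(math.log(2) / (100 / 60), rel=1e-12)
        k5 = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=5.0)
        assert k5.beta == pytest.approx(math.log(10) * 12, rel=1e-12)

    def test_sampled_parameter_ranges(self, rng):
        draws = [sample_gene_kinetics(rng, 100.0) for _ in range(10_000)]
        alphas = np.array([k.alpha for k in draws])
        kds = np.array([k.kd for k in draws])
        sts = np.array([k.splicing_time for k in draws])
        assert 100.0 <= alphas.min() and alphas.max() <= 200.0
        assert 0.05 <= kds.min() and kds.max() <= 0.25
        assert 5.0 <= sts.min() and sts.max() <= 10.0
        assert all(k.n == 2.0 for k in draws[:10])

    def test_nonpositive_half_life_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_gene_kinetics(rng, 0.0)


class TestSteadyState:
    def test_zero_tf_gives_zero(self):
        k = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=7)
        assert steady_state(k, 0.0) == (0.0, 0.0)

    def test_half_maximal_at_kd(self):
        k = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=7)
        u, s = steady_state(k, k.kd)
        assert u == pytest.approx(k.alpha / (2 * k.beta))
        assert s == pytest.approx(k.alpha / (2 * k.gamma))

    def test_saturation_limit(self):
        k = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=7)
        u, _ = steady_state(k, 100 * k.kd)
        assert u == pytest.approx(k.alpha / k.beta, rel=1e-4)


class TestODE:
    def test_constant_tf_stays_at_fixed_point(self):
        k = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=7)
        wf = TFWaveformParams(a_basal=0.2, a_max=0.2)
        grid = SimulationGrid(duration=20.0, dt=0.01)
        tr = simulate_ode(k, wf, grid)
        u0, s0 = steady_state(k, 0.2)
        assert np.max(np.abs(tr.u - u0)) / u0 < 1e-6
        assert np.max(np.abs(tr.s - s0)) / s0 < 1e-6

    def test_spliced_lags_unspliced_lags_tf(self):
        # long half-life: the mature-mRNA peak trails the pre-mRNA peak by
        # more than the pre-mRNA trails the TF peak
        k = GeneKinetics(alpha=150, n=2, kd=0.15, half_life=1000, splicing_time=7)
        wf = TFWaveformParams()
        grid = SimulationGrid(duration=20.0, dt=0.001)
        tr = simulate_ode(k, wf, grid)
        window = (tr.times >= wf.period) & (tr.times <= 2 * wf.period)
        t = tr.times[window]
        lag_u = t[np.argmax(tr.u[window])] - t[np.argmax(tr.tf[window])]
        lag_s = t[np.argmax(tr.s[window])] - t[np.argmax(tr.u[window])]
        assert lag_s > lag_u >= 0.0


class TestTauLeap:
    def test_seeded_determinism(self):
        k = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=7)
        wf = TFWaveformParams(noise_enabled=True)
        grid = SimulationGrid(duration=2.0, dt=0.001)
        a = simulate_tau_leap(k, wf, grid, rng=np.random.default_rng(42))
        b = simulate_tau_leap(k, wf, grid, rng=np.random.default_rng(42))
        assert np.array_equal(a.u, b.u) and np.array_equal(a.s, b.s)
        assert np.array_equal(a.tf, b.tf)

    def test_step_count_matches_grid(self):
        grid = SimulationGrid(duration=20.0, dt=0.001)
        assert grid.n_steps == 20_000
        k = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=7)
        tr = simulate_tau_leap(k, TFWaveformParams(), SimulationGrid(duration=1.0, dt=0.01),
                               rng=np.random.default_rng(0))
        assert len(tr.times) == 101

    def test_nonpositive_omega_rejected(self):
        k = GeneKinetics(alpha=150, n=2, kd=0.1, half_life=100, splicing_time=7)
        with pytest.raises(ValueError):
            simulate_tau_leap(k, TFWaveformParams(), SimulationGrid(duration=1.0, dt=0.01),
                              omega=0.0, rng=np.random.default_rng(0))


class TestThinning:
    def test_identity_and_zero(self, rng):
        counts = np.array([0, 1, 10, 1000])
        assert np.array_equal(thin_detection(counts, 1.0, rng), counts)
        assert np.array_equal(thin_detection(counts, 0.0, rng), np.zeros(4, dtype=int))

    def test_preserves_expectation(self, rng):
        draws = thin_detection(np.full(10_000, 1000), 0.1, rng)
        se = math.sqrt(1000 * 0.1 * 0.9 / 10_000)
        assert abs(draws.mean() - 100.0) < 3 * se

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            thin_detection([1, 2], 1.5, rng)
        with pytest.raises(ValueError):
            thin_detection([-1], 0.5, rng)


class TestEnsembleBenchmark:
    def test_requires_two_cells(self):
        with pytest.raises(ValueError):
            ensemble_benchmark([100.0], TFWaveformParams(), n_cells=1)

    def test_seed_reproducibility(self):
        wf = TFWaveformParams(noise_enabled=True)
        grid = SimulationGrid(duration=12.0, dt=0.005)
        a = ensemble_benchmark([100.0, 1000.0], wf, n_cells=4, seed=7, grid=grid)
        b = ensemble_benchmark([100.0, 1000.0], wf, n_cells=4, seed=7, grid=grid)
        assert np.array_equal(a.corr_u_mean, b.corr_u_mean)
        assert np.array_equal(a.corr_s_mean, b.corr_s_mean)
        assert a.regulon_corr_u == b.regulon_corr_u

    def test_unspliced_tracks_tf_better_for_long_lived_targets(self):
        wf = TFWaveformParams(noise_enabled=True)
        grid = SimulationGrid(duration=12.0, dt=0.005)
        bench = ensemble_benchmark([1000.0, 1000.0], wf, n_cells=6, seed=3, grid=grid)
        assert np.all(bench.corr_u_mean > bench.corr_s_mean)
        assert bench.regulon_corr_u > bench.regulon_corr_s

    def test_analysis_window_spans_whole_periods(self):
        times = SimulationGrid(duration=20.0, dt=0.001).times
        mask = _analysis_window(times, 5.5, 1.0)
        selected = times[mask]
        assert selected[0] == pytest.approx(5.5)
        # two full periods fit into the 14.5 h tail
        assert selected[-1] == pytest.approx(5.5 + 2 * 5.5, abs=0.002)

    def test_detection_sweep_nested_thinning_is_ordered(self):
        wf = TFWaveformParams(noise_enabled=True)
        grid = SimulationGrid(duration=12.0, dt=0.005)
        res = detection_sweep(100.0, wf, [0.2, 0.05], n_cells=4, seed=2, grid=grid)
        ps = [r[0] for r in res]
        assert ps == sorted(ps, reverse=True)
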