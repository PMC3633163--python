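"""Simulator: unit operations, determinism, oracles, symmetries."""

import numpy as np
import pytest

from saccsim import (
    ConfigurationError,
    ModelParameters,
    evolve_train,
    leak_decay,
    moving_bin_counts,
    poisson_spikes,
    response_peak,
    run_simulation,
    single_saccade,
    spike_jump,
    stationary_protocol,
)


class TestPoissonSpikes:
    def test_zero_rate_never_fires(self):
        rng = np.random.default_rng(0)
        rates = np.zeros(100)
        for _ in range(50):
            assert not poisson_spikes(rates, 0.1, rng).any()

    def test_empirical_rate(self):
        # single neuron at 50 spikes/s, dt=0.1 ms, 10^6 steps = 100 s
        rng = np.random.default_rng(1)
        n = sum(
            poisson_spikes(np.array([50.0]), 0.1, rng)[0] for _ in range(0)
        )
        p = 50.0 * 0.1 * 1e-3
        draws = rng.random(1_000_000) < p
        rate = draws.sum() / 100.0
        assert abs(rate - 50.0) < 3 * np.sqrt(50.0 / 100.0)

    def test_determinism_and_dt_guard(self):
        a = poisson_spikes(np.full(50, 40.0), 0.1, np.random.default_rng(9))
        b = poisson_spikes(np.full(50, 40.0), 0.1, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ConfigurationError):
            poisson_spikes(np.array([2000.0]), 1.0, np.random.default_rng(0))


class TestMembraneOperations:
    def test_leak_decay(self):
        assert leak_decay(-58.0, 30.0, 30.0, -70.0) == pytest.approx(
            -70.0 + 12.0 * np.exp(-1.0), rel=1e-12
        )
        assert leak_decay(-70.0, 5.0, 30.0, -70.0) == pytest.approx(-70.0)
        assert leak_decay(-60.0, 0.0, 30.0, -70.0) == pytest.approx(-60.0)

    def test_spike_jump(self):
        assert spike_jump(-70.0, 0.15, 1.0, 1.0, 0.0, 30.0) == pytest.approx(-69.65)
        assert spike_jump(-60.0, 0.15, 1.0, 0.0, 0.0, 30.0) == pytest.approx(-60.0)

    def test_repeated_jumps_approach_reversal(self):
        V = -70.0
        prev = V
        for _ in range(10_000):
            V = spike_jump(V, 0.15, 1.0, 1.0, 0.0, 30.0)
            assert prev < V <= 0.0
            prev = V
        assert V == pytest.approx(0.0, abs=1e-6)


class TestRunSimulation:
    def test_zero_duration_empty(self, params):
        from saccsim import Protocol

        res = run_simulation(params, Protocol(0.0, [], [], [0.0]), 0)
        assert res.spikes.count("lgn") == 0 and res.spikes.count("v1") == 0

    def test_null_stimulus_silent_and_recovering(self, params):
        proto = stationary_protocol(500.0, 0.0)
        res = run_simulation(params, proto, 3, initial_S=np.full(params.N, 0.5))
        assert res.spikes.count("lgn") == 0
        assert res.spikes.count("v1") == 0
        # strengths relax toward 1 with no input
        expected = 1.0 - 0.5 * np.exp(-500.0 / params.tau_S)
        np.testing.assert_allclose(res.final_S, expected, rtol=1e-9)

    def test_same_seed_bit_identical(self, params):
        proto = stationary_protocol(2000.0, params.A).with_events(
            single_saccade(1000.0, 2.0)
        )
        a = run_simulation(params, proto, 77)
        b = run_simulation(params, proto, 77, record_synapses=True)
        np.testing.assert_array_equal(a.spikes.lgn_times, b.spikes.lgn_times)
        np.testing.assert_array_equal(a.spikes.lgn_neurons, b.spikes.lgn_neurons)
        np.testing.assert_array_equal(a.spikes.v1_times, b.spikes.v1_times)
        c = run_simulation(params, proto, 78)
        assert not (
            c.spikes.count("lgn") == a.spikes.count("lgn")
            and np.array_equal(c.spikes.lgn_times, a.spikes.lgn_times)
        )

    def test_membrane_bounds(self, params):
        proto = stationary_protocol(1500.0, params.A)
        res = run_simulation(
            params, proto, 5, record_membrane=True, sample_every_ms=1.0
        )
        V = res.membrane_trace
        assert V.max() <= params.V_th + 1e-9  # sampled after threshold/reset
        assert V.min() >= params.V0 - 1e-9

    def test_lgn_rate_matches_profile(self, params):
        from saccsim import input_rate_profile, neuron_positions

        proto = stationary_protocol(20_000.0, params.A)
        res = run_simulation(params, proto, 21)
        R = input_rate_profile(
            neuron_positions(params), 0.0, params.A, params.sigma1, params.L
        )
        counts = np.bincount(res.spikes.lgn_neurons, minlength=params.N)
        total_expected = R.sum() * 20.0  # rates in spikes/s * 20 s
        assert abs(counts.sum() - total_expected) / total_expected < 0.02
        center = np.argmax(R)
        assert abs(counts[center] / 20.0 - R[center]) < 4 * np.sqrt(R[center] / 20.0)


class TestSynapseOracle:
    def test_time_stepped_matches_event_driven_closed_form(self, params):
        """The recorded strength trajectory of every synapse coincides with
        the exact event-driven evolution of its recorded spike train."""
        proto = stationary_protocol(2000.0, params.A).with_events(
            single_saccade(1000.0, 2.0)
        )
        res = run_simulation(
            params, proto, 13, record_synapses=True, sample_every_ms=50.0
        )
        worst = 0.0
        for j in range(0, params.N, 7):
            train = res.spikes.neuron_train("lgn", j)
            traj = evolve_train(train, params.f, params.tau_S, t_end=2000.0)
            dev = np.abs(
                traj.S_at(res.synapse_sample_times) - res.synapse_trace[:, j]
            ).max()
            worst = max(worst, dev)
        assert worst < 1e-9  # same closed forms; agreement is exact

    def test_strengths_stay_in_unit_interval(self, params):
        proto = stationary_protocol(3000.0, params.A)
        res = run_simulation(
            params, proto, 17, record_synapses=True, sample_every_ms=10.0
        )
        assert np.all(res.synapse_trace > 0.0)
        assert np.all(res.synapse_trace <= 1.0)
        assert np.all(res.final_S > 0.0) and np.all(res.final_S <= 1.0)


class TestPhenomenology:
    def test_adapted_state_mostly_quiet_fresh_synapses_fire(self, params):
        """Prolonged fixation depresses the drive to near threshold; resetting
        the synapses to full strength reignites firing within 50 ms."""
        warm = run_simulation(params, stationary_protocol(2500.0, params.A), 23)
        late = warm.spikes.v1_times >= 1000.0
        adapted_rate = late.sum() / 1.5  # population spikes/s
        fresh = run_simulation(
            params,
            stationary_protocol(200.0, params.A),
            24,
            initial_V=warm.final_V,
            initial_S=np.ones(params.N),
        )
        early = fresh.spikes.v1_times <= 50.0
        assert early.sum() > 50
        assert early.sum() / 0.05 > 20 * adapted_rate

    def test_timestep_robustness_of_saccade_peak(self, params):
        """Halving dt changes the saccade-evoked peak by < 10% (mean over seeds)."""
        peaks = {}
        for dt in (0.1, 0.05):
            p = params.replace(dt=dt)
            proto = stationary_protocol(2400.0, p.A).with_events(
                single_saccade(2000.0, 2.0)
            )
            vals = []
            for seed in range(10):
                res = run_simulation(p, proto, 3000 + seed)
                trace = moving_bin_counts(res.spikes, 2400.0)
                vals.append(response_peak(trace, 2000.0))
            peaks[dt] = np.mean(vals)
        assert abs(peaks[0.05] - peaks[0.1]) / peaks[0.1] < 0.10

    def test_saccade_direction_symmetry(self, params):
        """+Delta_M and -Delta_M displacements evoke statistically equal peaks."""
        means = {}
        for direction in (+1, -1):
            vals = []
            for seed in range(8):
                proto = stationary_protocol(2400.0, params.A).with_events(
                    single_saccade(2000.0, 2.0, direction)
                )
                res = run_simulation(params, proto, 4000 + seed)
                vals.append(
                    response_peak(moving_bin_counts(res.spikes, 2400.0), 2000.0)
                )
            means[direction] = np.mean(vals)
        assert abs(means[1] - means[-1]) / means[1] < 0.25

    def test_translation_equivariance_of_population_response(self, params):
        """Displacing the whole protocol on the ring leaves the population
        response statistically unchanged."""
        acts = []
        for x0 in (0.0, 5.0):
            vals = []
            for seed in range(6):
                proto = stationary_protocol(2400.0, params.A).with_events(
                    single_saccade(2000.0, 2.0)
                )
                proto.x0 = x0
                res = run_simulation(params, proto, 5000 + seed)
                vals.append(
                    response_peak(moving_bin_counts(res.spikes, 2400.0), 2000.0)
                )
            acts.append(np.mean(vals))
        assert abs(acts[0] - acts[1]) / acts[0] < 0.25
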