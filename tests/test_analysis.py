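"""Response measures: binning, peaks, fading, sweeps."""

import numpy as np
import pytest

from saccsim import (
    ModelParameters,
    ResponseTrace,
    average_activity,
    fading_time,
    flash_interval_analysis,
    flash_onset_peak,
    frequency_sweep,
    magnitude_sweep,
    moving_bin_counts,
    per_neuron_bin_counts,
    phase_diagram,
    response_peak,
    run_simulation,
    sensitivity_curve,
    single_saccade,
    stationary_protocol,
    velocity_sweep,
)
from saccsim.simulator import SpikeTable


def _table(v1_times, v1_neurons=None):
    v1_times = np.asarray(v1_times, dtype=float)
    if v1_neurons is None:
        v1_neurons = np.zeros(v1_times.size, dtype=np.int64)
    return SpikeTable(
        np.empty(0, dtype=np.int64), np.empty(0), np.asarray(v1_neurons), v1_times
    )


class TestMovingBin:
    def test_empty_table_all_zero(self):
        trace = moving_bin_counts(_table([]), 1000.0)
        assert trace.counts.sum() == 0
        assert trace.times[0] == 0.0

    def test_single_spike_window_arithmetic(self):
        # spike at t=100: exactly the windows starting in (50, 100] see it
        trace = moving_bin_counts(_table([100.0]), 300.0, t_bin=50.0, step=1.0)
        hit = trace.times[trace.counts == 1]
        assert hit.min() == 51.0 and hit.max() == 100.0

    def test_non_overlapping_bins_conserve_total(self, params):
        res = run_simulation(params, stationary_protocol(1000.0, params.A), 31)
        for layer in ("lgn", "v1"):
            trace = moving_bin_counts(
                res.spikes, 1000.0, t_bin=50.0, step=50.0, layer=layer
            )
            assert trace.counts.sum() == res.spikes.count(layer)

    def test_per_neuron_counts_sum_to_population(self, params):
        res = run_simulation(params, stationary_protocol(600.0, params.A), 32)
        prof = per_neuron_bin_counts(res.spikes, 100.0, 50.0, params.N, "lgn")
        trace = moving_bin_counts(res.spikes, 600.0, layer="lgn")
        assert prof.sum() == trace.counts[int(100.0)]


class TestScalarMeasures:
    def test_peak_of_zero_trace(self):
        trace = ResponseTrace(np.arange(500.0), np.zeros(500, dtype=int), 50.0, 1.0)
        assert response_peak(trace, 100.0) == 0.0

    def test_peak_window_selection(self):
        counts = np.zeros(500, dtype=int)
        counts[120] = 7
        counts[400] = 9  # outside the 200 ms window after t=100
        trace = ResponseTrace(np.arange(500.0), counts, 50.0, 1.0)
        assert response_peak(trace, 100.0) == 7.0

    def test_fading_flags(self):
        times = np.arange(1000.0)
        silent = ResponseTrace(times, np.zeros(1000, dtype=int), 50.0, 1.0)
        r = fading_time(silent, 100.0)
        assert not r.responded and r.time == 0.0
        never = ResponseTrace(times, np.ones(1000, dtype=int), 50.0, 1.0)
        r = fading_time(never, 100.0)
        assert r.responded and not r.faded

    def test_fading_simple_case(self):
        counts = np.zeros(1000, dtype=int)
        counts[150:400] = 5  # peak region then silence from 400
        trace = ResponseTrace(np.arange(1000.0), counts, 50.0, 1.0)
        r = fading_time(trace, 100.0)
        assert r.faded and r.time == 300.0  # first zero window starts at 400

    def test_average_activity(self):
        trace = ResponseTrace(np.arange(2000.0), np.full(2000, 3), 50.0, 1.0)
        assert average_activity(trace) == 3.0
        zero = ResponseTrace(np.arange(2000.0), np.zeros(2000, dtype=int), 50.0, 1.0)
        assert average_activity(zero) == 0.0
        with pytest.raises(ValueError):
            average_activity(ResponseTrace(np.arange(100.0), np.zeros(100), 50.0, 1.0))

    def test_sensitivity_curve(self):
        F = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(sensitivity_curve(F, 2.5 * F + 1), 2.5)
        assert np.allclose(sensitivity_curve(F, np.full(4, 7.0)), 0.0)
        with pytest.raises(ValueError):
            sensitivity_curve(F[:2], np.zeros(2))


class TestSweeps:
    def test_frequency_sweep_shapes_and_activity_rises(self, params):
        sw = frequency_sweep(
            params, [1.0, 3.0, 6.0], duration=8000.0, seeds=range(3)
        )
        assert sw.samples["activity"].shape == (3, 3)
        assert sw.extras["sensitivity"].shape == (3,)
        act = sw.mean("activity")
        assert act[-1] > act[0] > 0  # more saccades, more activity

    def test_magnitude_sweep_rises_then_saturates(self):
        sw = magnitude_sweep(
            delta_M_grid=(1.0, 3.0, 9.0), seeds=range(3), warmup=1500.0, post=500.0
        )
        peaks = sw.mean("peak")
        assert peaks[1] > peaks[0]
        # deep in saturation the response no longer grows proportionally
        assert peaks[2] < 2.0 * peaks[1]

    def test_velocity_sweep_monotone_rise(self):
        sw = velocity_sweep(
            velocity_grid=(0.02, 0.4), seeds=range(3), warmup=1500.0, post=500.0
        )
        peaks = sw.mean("peak")
        assert peaks[1] > peaks[0]

    def test_flash_interval_peak_and_strength_decline(self, params):
        sw = flash_interval_analysis(
            params,
            intervals=[50.0, 900.0],
            seeds=range(3),
            n_warm_cycles=1,
        )
        s = sw.mean("mean_strength")
        assert 0.0 < s[1] < s[0] <= 1.0  # later saccade sees more depression
        p = sw.mean("peak")
        assert p[0] > p[1]
        assert sw.extras["stationary_baseline"] >= 0.0
        with pytest.raises(ValueError):
            flash_interval_analysis(params, intervals=[2000.0], seeds=range(1))

    def test_flash_onset_peak_grows_with_off_duration(self, params):
        short = flash_onset_peak(params, 100.0, seeds=range(3), n_cycles=2).mean()
        long = flash_onset_peak(params, 1000.0, seeds=range(3), n_cycles=2).mean()
        assert long > short

    def test_phase_diagram_structure(self, params):
        res = phase_diagram(
            params,
            T_on_grid=[1000.0],
            T_off_grid=[500.0, 1000.0],
            duration=15_000.0,
            seeds=range(2),
        )
        assert res["peak"].shape == (1, 2)
        assert np.all(np.isfinite(res["peak"]))
        assert res["stationary_peak"] > 0
        assert np.all(res["ratio"] > 0)
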