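"""Response measures and parameter-sweep experiments.

The response measure throughout is the population spike count N_sp of a
layer in a moving 50 ms window (analysis step 1 ms).  On top of it sit
the derived quantities — response peaks after an event, fading times,
average activity and its sensitivity to microsaccade frequency — and
the sweep experiments over frequency, magnitude, velocity and flash
timing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seeding import child_rng, child_seed
from .params import ModelParameters
from .protocols import (
    Protocol,
    flashing_protocol,
    poisson_saccades,
    single_saccade,
    stationary_protocol,
)
from .simulator import SpikeTable, run_simulation

__all__ = [
    "ResponseTrace",
    "FadingResult",
    "SweepResult",
    "moving_bin_counts",
    "per_neuron_bin_counts",
    "response_peak",
    "fading_time",
    "average_activity",
    "sensitivity_curve",
    "frequency_sweep",
    "magnitude_sweep",
    "velocity_sweep",
    "flash_interval_analysis",
    "flash_onset_peak",
    "phase_diagram",
]

PEAK_WINDOW_MS = 200.0  # search window for event-evoked peaks
DISCARD_MS = 500.0  # transient discarded from average activity


@dataclass
class ResponseTrace:
    """Population spike count per moving window.

    ``times`` are window *start* times on the analysis-step grid;
    ``counts[k]`` is the number of spikes in ``[times[k], times[k] + t_bin)``.
    """

    times: np.ndarray
    counts: np.ndarray
    t_bin: float
    step: float


@dataclass
class FadingResult:
    """Outcome of a fading measurement relative to an event.

    ``time`` is the delay from the event until the first empty window
    after the evoked peak; ``responded`` is False when no post-event
    activity existed at all, ``faded`` is False when activity never
    ceased within the trace.
    """

    time: float
    responded: bool
    faded: bool


@dataclass
class SweepResult:
    """One measurement matrix per swept parameter grid.

    ``samples[name]`` has shape (len(values), n_replicates); summary
    accessors report the replicate mean and standard deviation.
    """

    parameter: str
    values: np.ndarray
    samples: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        first = next(iter(self.samples.values()))
        return first.shape[1]

    def mean(self, name: str) -> np.ndarray:
        return self.samples[name].mean(axis=1)

    def std(self, name: str) -> np.ndarray:
        return self.samples[name].std(axis=1, ddof=1) if self.n_replicates > 1 else np.zeros(len(self.values))


# -- binning ----------------------------------------------------------


def moving_bin_counts(
    spikes: SpikeTable,
    duration: float,
    t_bin: float = 50.0,
    step: float = 1.0,
    layer: str = "v1",
) -> ResponseTrace:
    """Population count in [t, t + t_bin) for every start t on the step grid.

    With ``step == t_bin`` the windows tile the trace and the counts sum
    to the total spike count of the layer.
    """
    if t_bin <= 0 or step <= 0:
        raise ValueError("t_bin and step must be positive")
    times = spikes.times(layer)
    n_fine = int(round(duration / step))
    fine, _ = np.histogram(times, bins=n_fine, range=(0.0, n_fine * step))
    w = max(int(round(t_bin / step)), 1)
    csum = np.concatenate([[0], np.cumsum(fine)])
    n_windows = max(n_fine - w + 1, 0)
    counts = csum[w : w + n_windows] - csum[:n_windows]
    starts = np.arange(n_windows) * step
    return ResponseTrace(starts, counts, t_bin, step)


def per_neuron_bin_counts(
    spikes: SpikeTable,
    t_start: float,
    t_bin: float,
    N: int,
    layer: str = "v1",
) -> np.ndarray:
    """Spike count of each neuron in [t_start, t_start + t_bin): the
    spatial response profile of the layer in one window."""
    t = spikes.times(layer)
    idx = spikes.neurons(layer)[(t >= t_start) & (t < t_start + t_bin)]
    return np.bincount(idx, minlength=N)


# -- scalar measures --------------------------------------------------


def response_peak(
    trace: ResponseTrace, event_time: float, window: float = PEAK_WINDOW_MS
) -> float:
    """Maximum moving-bin count among windows starting in
    (event_time, event_time + window]."""
    if window <= 0:
        raise ValueError("window must be positive")
    if event_time + window > trace.times[-1] + trace.step:
        warnings.warn("peak window extends beyond trace end; truncated")
    mask = (trace.times > event_time) & (trace.times <= event_time + window)
    if not mask.any():
        return 0.0
    return float(trace.counts[mask].max())


def fading_time(
    trace: ResponseTrace, event_time: float, window: float = PEAK_WINDOW_MS
) -> FadingResult:
    """Delay from the event until the response has completely faded.

    The evoked peak is located within ``window`` after the event; fading
    is the first window after the peak whose 50 ms count is zero.
    """
    after = trace.times > event_time
    if not after.any() or trace.counts[after].max() == 0:
        return FadingResult(0.0, responded=False, faded=True)
    peak_mask = (trace.times > event_time) & (trace.times <= event_time + window)
    k_peak = np.flatnonzero(peak_mask)[np.argmax(trace.counts[peak_mask])]
    later = np.flatnonzero((np.arange(trace.times.size) > k_peak) & (trace.counts == 0))
    if later.size == 0:
        return FadingResult(float(trace.times[-1] - event_time), responded=True, faded=False)
    return FadingResult(float(trace.times[later[0]] - event_time), responded=True, faded=True)


def average_activity(trace: ResponseTrace, discard: float = DISCARD_MS) -> float:
    """Mean moving-bin count after discarding the initial transient."""
    mask = trace.times >= discard
    if not mask.any():
        raise ValueError("trace shorter than the discarded transient")
    return float(trace.counts[mask].mean())


def sensitivity_curve(values: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Finite-difference slope of activity vs. the swept parameter
    (central differences; one-sided at the edges)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least three grid points for a slope")
    return np.gradient(np.asarray(means, dtype=float), values)


# -- sweep experiments ------------------------------------------------


def _run_trace(params, protocol, kernel_seed, **kw):
    res = run_simulation(params, protocol, kernel_seed, **kw)
    trace = moving_bin_counts(res.spikes, protocol.duration, params.T_bin, 1.0, "v1")
    return res, trace


def frequency_sweep(
    params: ModelParameters,
    F_grid,
    delta_M: float = 2.0,
    mode: str = "poisson",
    duration: float = 30_000.0,
    seeds=range(20),
    discard: float = DISCARD_MS,
) -> SweepResult:
    """Average activity vs. microsaccade rate F (Hz), with sensitivity.

    Saccade trains (Poisson or periodic) run over a stationary stimulus
    for ``duration`` ms; activity is the mean moving-bin count after the
    onset transient.  Returns measures ``activity`` and extras
    ``sensitivity`` (slope of the mean curve over the grid).
    """
    from .protocols import periodic_saccades

    F_grid = np.asarray(list(F_grid), dtype=float)
    seeds = list(seeds)
    act = np.empty((F_grid.size, len(seeds)))
    for a, F in enumerate(F_grid):
        for b, seed in enumerate(seeds):
            rng = child_rng(seed, 11, a)
            base = stationary_protocol(duration, params.A)
            if mode == "poisson":
                events = poisson_saccades(F, delta_M, duration, rng)
            elif mode == "periodic":
                events = periodic_saccades(F, delta_M, duration, rng=rng)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            proto = base.with_events(events)
            _, trace = _run_trace(params, proto, child_seed(seed, 12, a))
            act[a, b] = average_activity(trace, discard)
    out = SweepResult("F", F_grid, {"activity": act})
    out.extras["sensitivity"] = sensitivity_curve(F_grid, act.mean(axis=1))
    return out


def _single_saccade_peak(params, delta_M, seed, key, warmup, post, window, duration_ms=0.0):
    total = warmup + post
    proto = stationary_protocol(total, params.A)
    if delta_M > 0:
        ev = single_saccade(warmup, delta_M)
        if duration_ms > 0:
            ev = [type(ev[0])(warmup, delta_M, 1, duration_ms)]
        proto = proto.with_events(ev)
    _, trace = _run_trace(params, proto, child_seed(seed, *key))
    return response_peak(trace, warmup, window)


def magnitude_sweep(
    params: ModelParameters | None = None,
    delta_M_grid=(0.5, 1.0, 2.0, 3.0, 4.5, 6.0, 9.0),
    seeds=range(20),
    warmup: float = 2000.0,
    post: float = 1000.0,
    window: float = PEAK_WINDOW_MS,
) -> SweepResult:
    """Post-saccade response peak vs. saccade magnitude.

    Defaults to the strong-drive configuration (g = 0.2, A = 100) used
    for the saturation experiment; each point is the peak after a single
    saccade from the adapted state, averaged over seeds.
    """
    if params is None:
        params = ModelParameters(g=0.2, A=100.0)
    grid = np.asarray(list(delta_M_grid), dtype=float)
    seeds = list(seeds)
    peaks = np.empty((grid.size, len(seeds)))
    for a, dM in enumerate(grid):
        for b, seed in enumerate(seeds):
            peaks[a, b] = _single_saccade_peak(
                params, dM, seed, (21, a), warmup, post, window
            )
    return SweepResult("delta_M", grid, {"peak": peaks})


def velocity_sweep(
    params: ModelParameters | None = None,
    velocity_grid=(0.02, 0.05, 0.1, 0.2, 0.4, 0.8),
    seeds=range(20),
    warmup: float = 2000.0,
    post: float = 1000.0,
    window: float = PEAK_WINDOW_MS,
    saccade_duration: float = 15.0,
) -> SweepResult:
    """Response peak vs. saccade velocity at fixed 15 ms duration.

    Velocity is in position units per ms; the traversed magnitude is
    ``v * 15`` and the dot moves linearly during the event.
    """
    if params is None:
        params = ModelParameters(g=0.2, A=100.0)
    grid = np.asarray(list(velocity_grid), dtype=float)
    seeds = list(seeds)
    peaks = np.empty((grid.size, len(seeds)))
    for a, v in enumerate(grid):
        dM = v * saccade_duration
        for b, seed in enumerate(seeds):
            peaks[a, b] = _single_saccade_peak(
                params, dM, seed, (31, a), warmup, post, window,
                duration_ms=saccade_duration,
            )
    return SweepResult("velocity", grid, {"peak": peaks})


def flash_interval_analysis(
    params: ModelParameters,
    intervals,
    T_on: float = 1000.0,
    T_off: float = 1000.0,
    delta_M: float = 1.0,
    seeds=range(20),
    n_warm_cycles: int = 2,
    window: float = PEAK_WINDOW_MS,
    sample_every_ms: float = 5.0,
    weight_by_rate: bool = False,
) -> SweepResult:
    """Saccade-evoked peak and mean strength vs. the saccade-to-flash-onset lag.

    The flash cycle runs ``n_warm_cycles`` full periods to reach its
    cyclic steady state; a single saccade is then placed ``interval`` ms
    after the next flash onset.  Measures: ``peak`` (response peak) and
    ``mean_strength`` (network-averaged synaptic strength just before
    the saccade).  Extras: ``grid_mean`` (mean peak over the interval
    grid, the all-lags average) and ``stationary_baseline`` (the same
    saccade from the stationary adapted state).

    ``mean_strength`` is the unweighted mean over all N synapses by
    default; with ``weight_by_rate`` it is weighted by each synapse's
    pre-saccade input rate, emphasising the stimulated subpopulation.
    """
    from .network import input_rate_profile, neuron_positions
    intervals = np.asarray(list(intervals), dtype=float)
    if np.any(intervals < 0) or np.any(intervals > T_on):
        raise ValueError("intervals must lie in [0, T_on]")
    seeds = list(seeds)
    cycle = T_on + T_off
    t_on_meas = n_warm_cycles * cycle
    peaks = np.empty((intervals.size, len(seeds)))
    meanS = np.empty_like(peaks)
    for a, lag in enumerate(intervals):
        t_m = t_on_meas + lag
        duration = t_on_meas + T_on + max(T_off, window + 100.0)
        duration = np.ceil(duration)
        for b, seed in enumerate(seeds):
            proto = flashing_protocol(T_on, T_off, duration, params.A).with_events(
                single_saccade(t_m, delta_M)
            )
            res, trace = _run_trace(
                params, proto, child_seed(seed, 41, a),
                record_synapses=True, sample_every_ms=sample_every_ms,
            )
            peaks[a, b] = response_peak(trace, t_m, window)
            k = np.searchsorted(res.synapse_sample_times, t_m, side="right") - 1
            row = res.synapse_trace[max(k, 0)]
            if weight_by_rate:
                R = input_rate_profile(
                    neuron_positions(params), 0.0, params.A, params.sigma1, params.L
                )
                meanS[a, b] = float(np.average(row, weights=R))
            else:
                meanS[a, b] = float(row.mean())
    out = SweepResult(
        "t_m - t_on", intervals, {"peak": peaks, "mean_strength": meanS}
    )
    out.extras["grid_mean"] = float(peaks.mean())
    base = np.empty(len(seeds))
    for b, seed in enumerate(seeds):
        base[b] = _single_saccade_peak(
            params, delta_M, seed, (42, 0), t_on_meas + T_on, max(T_off, window + 100.0), window
        )
    out.extras["stationary_baseline"] = float(base.mean())
    return out


def flash_onset_peak(
    params: ModelParameters,
    T_off: float,
    T_on: float = 1000.0,
    seeds=range(20),
    n_cycles: int = 4,
    window: float = PEAK_WINDOW_MS,
) -> np.ndarray:
    """Per-seed mean response peak after flash onsets (no saccades).

    Every onset after the first cycle is preceded by a full off-phase of
    length T_off.  ``T_off = 0`` degenerates to the stationary stimulus
    and measures the adapted-state activity instead.
    """
    seeds = list(seeds)
    out = np.empty(len(seeds))
    for b, seed in enumerate(seeds):
        if T_off == 0:
            proto = stationary_protocol(n_cycles * T_on, params.A)
            _, trace = _run_trace(params, proto, child_seed(seed, 51))
            out[b] = response_peak(trace, 2000.0, window)
            continue
        duration = n_cycles * (T_on + T_off)
        proto = flashing_protocol(T_on, T_off, duration, params.A)
        _, trace = _run_trace(params, proto, child_seed(seed, 51))
        onsets = [t for t in proto.flash_onsets if t > 0]
        out[b] = float(np.mean([response_peak(trace, t, window) for t in onsets]))
    return out


def _eligible_saccade_peaks(trace, events, window, on_segments=None, t_min=0.0):
    """Peaks for events after t_min whose window fits inside an on-phase."""
    peaks = []
    trace_end = trace.times[-1] + trace.step
    for ev in events:
        if ev.onset < t_min or ev.onset + window > trace_end:
            continue
        if on_segments is not None:
            ok = any(
                t0 <= ev.onset and ev.onset + window <= t1 for t0, t1, _ in on_segments
            )
            if not ok:
                continue
        peaks.append(response_peak(trace, ev.onset, window))
    return np.asarray(peaks)


def phase_diagram(
    params: ModelParameters,
    T_on_grid,
    T_off_grid,
    delta_M: float = 1.0,
    saccade_rate: float = 1.5,
    duration: float = 100_000.0,
    seeds=range(5),
    window: float = PEAK_WINDOW_MS,
) -> dict:
    """Saccade-evoked peak over the (T_on, T_off) plane, and its ratio
    to the stationary-stimulus peak.

    Saccades arrive in a Poisson train at ``saccade_rate`` Hz running
    through on- and off-phases alike; only saccades whose measurement
    window lies inside an on-phase (after the first full cycle) count.
    Returns matrices ``peak`` and ``ratio`` of shape
    (len(T_on_grid), len(T_off_grid)) plus the scalar
    ``stationary_peak``.
    """
    T_on_grid = np.asarray(list(T_on_grid), dtype=float)
    T_off_grid = np.asarray(list(T_off_grid), dtype=float)
    seeds = list(seeds)

    stat = np.empty(len(seeds))
    for b, seed in enumerate(seeds):
        rng = child_rng(seed, 61)
        proto = stationary_protocol(duration, params.A).with_events(
            poisson_saccades(saccade_rate, delta_M, duration, rng)
        )
        _, trace = _run_trace(params, proto, child_seed(seed, 62))
        p = _eligible_saccade_peaks(trace, proto.events, window, t_min=2000.0)
        stat[b] = p.mean() if p.size else 0.0
    stationary_peak = float(stat.mean())

    peak = np.empty((T_on_grid.size, T_off_grid.size))
    for a, T_on in enumerate(T_on_grid):
        for c, T_off in enumerate(T_off_grid):
            vals = []
            for b, seed in enumerate(seeds):
                rng = child_rng(seed, 63, a, c)
                proto = flashing_protocol(T_on, T_off, duration, params.A).with_events(
                    poisson_saccades(saccade_rate, delta_M, duration, rng)
                )
                _, trace = _run_trace(params, proto, child_seed(seed, 64, a, c))
                p = _eligible_saccade_peaks(
                    trace, proto.events, window,
                    on_segments=proto.segments, t_min=T_on + T_off,
                )
                if p.size:
                    vals.append(p.mean())
            peak[a, c] = float(np.mean(vals)) if vals else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = peak / stationary_peak if stationary_peak > 0 else np.full_like(peak, np.nan)
    return {
        "T_on": T_on_grid,
        "T_off": T_off_grid,
        "peak": peak,
        "ratio": ratio,
        "stationary_peak": stationary_peak,
    }
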