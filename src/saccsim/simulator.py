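"""Time-stepped simulation of the feedforward spiking network.

Input-layer (LGN) neurons fire Poisson trains whose rates track the
protocol's fixated-dot position and brightness; each spike of input
neuron j delivers a conductance pulse to every output (V1) neuron i,

    V_i <- V_i + (g W_ij S_j / tau_m) (V_E - V_i),

using the synapse's pre-depletion strength S_j, after which S_j is
depleted (S_j -> f S_j) and recovers exponentially.  Output neurons are
leaky integrators: V relaxes toward V0 with time constant tau_m and a
threshold crossing at V_th emits a spike and resets V to V_reset.

One step of width dt performs, in order: rate update from the protocol,
Bernoulli draw of input spikes (probability R_j dt each, at most one per
neuron per step), leak decay, pulse delivery, depletion, recovery, and
threshold/reset.  Input spikes are stamped at the start of their step
and output spikes at its end; synaptic recovery between events uses the
exact exponential, so the recorded strength trajectory coincides with
the event-driven closed form evaluated on the recorded input trains.

The hot loop is compiled with numba; a run is fully determined by its
seed regardless of which traces are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import connection_weights, neuron_positions
from .params import ConfigurationError, ModelParameters
from .protocols import Protocol

__all__ = [
    "SpikeTable",
    "SimulationResult",
    "poisson_spikes",
    "leak_decay",
    "spike_jump",
    "run_simulation",
]


# -- small library-level operations (also used standalone in analyses) --


def poisson_spikes(rates: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean spike indicators for one step by Bernoulli thinning.

    Each neuron fires independently with probability ``R_j * dt`` (rates
    in spikes/s, dt in ms); validity requires that probability < 0.1.
    """
    p = np.asarray(rates, dtype=float) * dt * 1e-3
    if p.max(initial=0.0) >= 0.1:
        raise ConfigurationError("dt too large for max rate: R*dt must stay < 0.1")
    return rng.random(p.shape) < p


def leak_decay(V, dt: float, tau_m: float, V0: float):
    """Exact leak-only relaxation toward rest over dt."""
    return V0 + (np.asarray(V, dtype=float) - V0) * np.exp(-dt / tau_m)


def spike_jump(V, g: float, W, S, VE: float, tau_m: float):
    """Conductance-pulse jump toward VE using the pre-jump potential."""
    V = np.asarray(V, dtype=float)
    return V + (g * np.asarray(W) * np.asarray(S) / tau_m) * (VE - V)


# -- containers -------------------------------------------------------


@dataclass
class SpikeTable:
    """Spike events of both layers: (neuron index, time in ms)."""

    lgn_neurons: np.ndarray
    lgn_times: np.ndarray
    v1_neurons: np.ndarray
    v1_times: np.ndarray

    def times(self, layer: str) -> np.ndarray:
        return getattr(self, f"{layer.lower()}_times")

    def neurons(self, layer: str) -> np.ndarray:
        return getattr(self, f"{layer.lower()}_neurons")

    def count(self, layer: str) -> int:
        return self.times(layer).size

    def neuron_train(self, layer: str, j: int) -> np.ndarray:
        """Sorted spike times of a single neuron."""
        mask = self.neurons(layer) == j
        return np.sort(self.times(layer)[mask])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "layer": ["lgn"] * self.count("lgn") + ["v1"] * self.count("v1"),
                "neuron_index": np.concatenate([self.lgn_neurons, self.v1_neurons]),
                "time_ms": np.concatenate([self.lgn_times, self.v1_times]),
            }
        )


@dataclass
class SimulationResult:
    """Everything a run produced, sufficient to reproduce it bit-exactly."""

    spikes: SpikeTable
    params: ModelParameters
    protocol: Protocol
    seed: int
    final_V: np.ndarray
    final_S: np.ndarray
    synapse_sample_times: np.ndarray | None = None
    synapse_trace: np.ndarray | None = None  # (n_samples, N)
    membrane_sample_times: np.ndarray | None = None
    membrane_trace: np.ndarray | None = None

    def mean_strength_at(self, t: float) -> float:
        """Network-averaged synaptic strength at the sample nearest t."""
        if self.synapse_trace is None:
            raise ValueError("run with record_synapses=True to sample strengths")
        k = int(np.argmin(np.abs(self.synapse_sample_times - t)))
        return float(self.synapse_trace[k].mean())


# -- kernel -----------------------------------------------------------


_BUCKETS = 1 << 16  # scheduling ring: 65536 steps = 6.5536 s at dt = 0.1


@njit(cache=False)
def _geom_failures(logq_j, far):
    """Failures before the first Bernoulli success, capped at ``far``."""
    u = np.random.random()
    if u <= 0.0:
        return np.int64(far)
    r = np.log(u) / logq_j
    if r >= far:
        return np.int64(far)
    return np.int64(r)


@njit(cache=False)
def _kernel(
    xf_steps,
    A_steps,
    positions,
    W,
    sigma1,
    L,
    g,
    f_dep,
    tau_S,
    tau_m,
    V0,
    VE,
    V_th,
    V_reset,
    dt,
    V,
    S,
    S_t,
    seed,
    lgn_i,
    lgn_t,
    v1_i,
    v1_t,
    samp_every,
    samp_t,
    S_samp,
    V_samp,
    record_membrane,
):
    # Event-driven evaluation of the per-step dynamics.  Per-neuron
    # Bernoulli(R_j*dt) spiking is sampled by geometric skips (exactly
    # equivalent in distribution), pending spikes live in a time-bucket
    # ring, and the leak is applied lazily with its exact exponential:
    # between input spikes every potential only decays toward V0 < V_th,
    # so threshold crossings can occur only in steps with a delivery.
    np.random.seed(seed)
    N = positions.shape[0]
    n_steps = xf_steps.shape[0]
    inv_s1sq = 1.0 / (sigma1 * sigma1)
    far = n_steps + _BUCKETS  # sentinel for "never"
    p = np.zeros(N)
    logq = np.zeros(N)  # log(1 - p_j), 0.0 when p_j == 0
    next_step = np.full(N, far, dtype=np.int64)
    head = np.full(_BUCKETS, -1, dtype=np.int64)
    nxt = np.full(N, -1, dtype=np.int64)
    last_xf = np.inf
    last_A = np.inf
    tV = 0.0  # time at which V is current (shared by all neurons)
    n_lgn = 0
    n_v1 = 0
    n_samp = 0
    overflow = 0
    todo = np.empty(N, dtype=np.int64)
    for k in range(n_steps):
        if xf_steps[k] != last_xf or A_steps[k] != last_A:
            # rate field changed: recompute probabilities, reschedule all
            last_xf = xf_steps[k]
            last_A = A_steps[k]
            c = last_A * dt * 1e-3
            for b in range(_BUCKETS):
                head[b] = -1
            for j in range(N):
                d = abs(positions[j] - last_xf)
                if d >= L:
                    d = 2.0 * L - d
                pj = c * np.exp(-d * d * inv_s1sq)
                p[j] = pj
                if pj > 0.0:
                    logq[j] = np.log1p(-pj)
                    # first success counting step k itself as a trial
                    next_step[j] = k + _geom_failures(logq[j], far)
                else:
                    next_step[j] = far
                if next_step[j] < n_steps:
                    b = min(next_step[j], k + _BUCKETS - 1) % _BUCKETS
                    nxt[j] = head[b]
                    head[b] = j
        # collect input spikes scheduled for this step
        b = k % _BUCKETS
        n_sp = 0
        j = head[b]
        head[b] = -1
        while j >= 0:
            jn = nxt[j]
            if next_step[j] == k:
                todo[n_sp] = j
                n_sp += 1
            elif next_step[j] < n_steps:
                # long-skip placeholder: push forward
                bb = min(next_step[j], k + _BUCKETS - 1) % _BUCKETS
                nxt[j] = head[bb]
                head[bb] = j
            j = jn
        t = k * dt
        t_end = (k + 1) * dt
        if n_sp > 0:
            # leak over the step, then sequential conductance jumps with
            # pre-depletion strengths, then threshold/reset at step end
            decay = np.exp(-(t_end - tV) / tau_m)
            for i in range(N):
                V[i] = V0 + (V[i] - V0) * decay
            tV = t_end
            for m in range(n_sp):
                j = todo[m]
                Sj = 1.0 - (1.0 - S[j]) * np.exp(-(t - S_t[j]) / tau_S)
                cj = g * Sj / tau_m
                for i in range(N):
                    V[i] += cj * W[i, j] * (VE - V[i])
                S[j] = f_dep * Sj
                S_t[j] = t
                if n_lgn < lgn_i.shape[0]:
                    lgn_i[n_lgn] = j
                    lgn_t[n_lgn] = t
                    n_lgn += 1
                else:
                    overflow = 1
                # reschedule this neuron's next spike
                next_step[j] = k + 1 + _geom_failures(logq[j], far)
                if next_step[j] < n_steps:
                    bb = min(next_step[j], k + _BUCKETS - 1) % _BUCKETS
                    nxt[j] = head[bb]
                    head[bb] = j
            for i in range(N):
                if V[i] >= V_th:
                    if n_v1 < v1_i.shape[0]:
                        v1_i[n_v1] = i
                        v1_t[n_v1] = t_end
                        n_v1 += 1
                    else:
                        overflow = 1
                    V[i] = V_reset
        if samp_every > 0 and (k + 1) % samp_every == 0:
            samp_t[n_samp] = t_end
            for j in range(N):
                S_samp[n_samp, j] = 1.0 - (1.0 - S[j]) * np.exp(
                    -(t_end - S_t[j]) / tau_S
                )
            if record_membrane:
                decay = np.exp(-(t_end - tV) / tau_m)
                for i in range(N):
                    V_samp[n_samp, i] = V0 + (V[i] - V0) * decay
            n_samp += 1
    # bring state up to date at the end of the run
    t_final = n_steps * dt
    decay = np.exp(-(t_final - tV) / tau_m)
    for i in range(N):
        V[i] = V0 + (V[i] - V0) * decay
    for j in range(N):
        S[j] = 1.0 - (1.0 - S[j]) * np.exp(-(t_final - S_t[j]) / tau_S)
        S_t[j] = t_final
    return n_lgn, n_v1, n_samp, overflow


# -- driver -----------------------------------------------------------


def run_simulation(
    params: ModelParameters,
    protocol: Protocol,
    seed: int,
    record_synapses: bool = False,
    record_membrane: bool = False,
    sample_every_ms: float = 10.0,
    initial_V: np.ndarray | None = None,
    initial_S: np.ndarray | None = None,
) -> SimulationResult:
    """Run the full network over a protocol; deterministic per seed.

    ``initial_V`` / ``initial_S`` warm-start the state (defaults: rest
    potential and fully recovered synapses), allowing runs to be
    chained.  Recording options never perturb the spike sequence.
    """
    if params.A * params.dt * 1e-3 >= 0.1:
        raise ConfigurationError("dt too large for peak rate A")
    positions = neuron_positions(params)
    W = connection_weights(positions, params.sigma2, params.L)
    xf_steps, A_steps = protocol.step_arrays(params.dt, params.L)
    n_steps = xf_steps.size

    V = np.full(params.N, params.V0) if initial_V is None else initial_V.astype(float).copy()
    S = np.ones(params.N) if initial_S is None else initial_S.astype(float).copy()
    if np.any(S <= 0) or np.any(S > 1):
        raise ValueError("initial synaptic strengths must lie in (0, 1]")
    S_t = np.zeros(params.N)

    # capacity estimates; overflow triggers a deterministic retry
    kernel_sum = float(np.exp(-(positions**2) / params.sigma1**2).sum())
    exp_lgn = kernel_sum * float(A_steps.sum()) * params.dt * 1e-3
    cap_lgn = int(1.6 * exp_lgn) + 10_000
    cap_v1 = max(100_000, int(exp_lgn) + 10_000)
    samp_every = int(round(sample_every_ms / params.dt)) if (record_synapses or record_membrane) else 0
    n_samp_max = n_steps // samp_every if samp_every else 0

    while True:
        V_run = V.copy()
        S_run = S.copy()
        St_run = S_t.copy()
        lgn_i = np.empty(cap_lgn, dtype=np.int64)
        lgn_t = np.empty(cap_lgn, dtype=np.float64)
        v1_i = np.empty(cap_v1, dtype=np.int64)
        v1_t = np.empty(cap_v1, dtype=np.float64)
        samp_t = np.empty(n_samp_max, dtype=np.float64)
        S_samp = np.empty((n_samp_max, params.N) if samp_every else (0, params.N))
        V_samp = np.empty((n_samp_max, params.N) if (samp_every and record_membrane) else (0, params.N))
        n_lgn, n_v1, n_samp, overflow = _kernel(
            xf_steps,
            A_steps,
            positions,
            W,
            params.sigma1,
            params.L,
            params.g,
            params.f,
            params.tau_S,
            params.tau_m,
            params.V0,
            params.VE,
            params.V_th,
            params.V_reset,
            params.dt,
            V_run,
            S_run,
            St_run,
            seed,
            lgn_i,
            lgn_t,
            v1_i,
            v1_t,
            samp_every,
            samp_t,
            S_samp,
            V_samp,
            record_membrane,
        )
        if not overflow:
            break
        cap_lgn *= 2
        cap_v1 *= 2

    if np.any(np.isnan(V_run)):
        raise FloatingPointError("membrane state became NaN during simulation")

    spikes = SpikeTable(
        lgn_i[:n_lgn].copy(),
        lgn_t[:n_lgn].copy(),
        v1_i[:n_v1].copy(),
        v1_t[:n_v1].copy(),
    )
    return SimulationResult(
        spikes=spikes,
        params=params,
        protocol=protocol,
        seed=int(seed),
        final_V=V_run,
        final_S=S_run,
        synapse_sample_times=samp_t[:n_samp].copy() if record_synapses else None,
        synapse_trace=S_samp[:n_samp].copy() if record_synapses else None,
        membrane_sample_times=samp_t[:n_samp].copy() if record_membrane else None,
        membrane_trace=V_samp[:n_samp].copy() if record_membrane else None,
    )
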