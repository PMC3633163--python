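"""Short-term depression kinetics.

A synapse carries a strength ``S`` in (0, 1].  Each presynaptic spike
depletes it multiplicatively, ``S -> f S``, and between spikes it
relaxes back toward 1 with time constant ``tau_S``:

    dS/dt = (1 - S) / tau_S            (between spikes)
    S(t + dt) = 1 - (1 - S(t)) e^(-dt/tau_S)

Both pieces have closed forms, so the trajectory for a known spike train
is evaluated exactly event by event — this module is the analytic
reference against which the time-stepped simulator is checked.

Steady states
-------------
Three characterisations of the adapted strength under sustained drive at
rate ``R`` are provided:

* ``steady_state_highrate`` — the high-rate approximation
  ``1 / (f + (1-f) R tau_S)`` (with ``R tau_S`` dimensionless).
* ``steady_state_periodic`` — the exact pre-spike fixed point under
  deterministic periodic spiking at interval ``1/R``.
* ``steady_state_poisson`` — the exact stationary *time average* under
  Poisson drive, ``1 / (1 + (1-f) R tau_S)``; by PASTA this also equals
  the mean strength seen by the spikes themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "deplete",
    "recover",
    "steady_state_highrate",
    "steady_state_periodic",
    "steady_state_poisson",
    "evolve_train",
    "TrainTrajectory",
    "fit_depression_params",
]


def deplete(S, f: float):
    """Multiplicative depletion at a presynaptic spike: S -> f*S."""
    return f * np.asarray(S, dtype=float) if np.ndim(S) else f * float(S)


def recover(S0, dt, tau_S: float):
    """Exact exponential recovery over an interval dt >= 0 (ms)."""
    S0 = np.asarray(S0, dtype=float)
    out = 1.0 - (1.0 - S0) * np.exp(-np.asarray(dt, dtype=float) / tau_S)
    if out.ndim == 0:
        return float(out)
    return out


def steady_state_highrate(R, f: float, tau_S: float):
    """High-rate adapted strength 1/(f + (1-f) R tau_S).

    ``R`` in spikes/s, ``tau_S`` in ms; the product is formed in
    consistent units.  Valid as an approximation only for large
    ``R * tau_S``; at R = 0 it returns 1/f > 1, outside the admissible
    strength range — callers probing low rates should use the exact
    forms instead.
    """
    R = np.asarray(R, dtype=float)
    out = 1.0 / (f + (1.0 - f) * R * tau_S * 1e-3)
    if out.ndim == 0:
        return float(out)
    return out


def steady_state_periodic(R, f: float, tau_S: float):
    """Exact pre-spike fixed point for periodic drive at rate R > 0.

    With inter-spike interval Delta = 1/R the depletion+recovery map
    ``S -> 1 - (1 - f S) e^(-Delta/tau_S)`` has the unique fixed point

        S* = (1 - e^(-Delta/tau_S)) / (1 - f e^(-Delta/tau_S)),

    which lies in (0, 1).
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("periodic steady state requires R > 0")
    q = np.exp(-1000.0 / (R * tau_S))  # Delta in ms = 1000/R
    out = (1.0 - q) / (1.0 - f * q)
    if out.ndim == 0:
        return float(out)
    return out


def steady_state_poisson(R, f: float, tau_S: float):
    """Exact stationary time-averaged strength under Poisson drive.

    Setting the mean of dS/dt to zero and using the PASTA property
    (Poisson spikes sample the time average) gives
    ``<S> = 1 / (1 + (1-f) R tau_S)``.
    """
    R = np.asarray(R, dtype=float)
    out = 1.0 / (1.0 + (1.0 - f) * R * tau_S * 1e-3)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class TrainTrajectory:
    """Exact strength trajectory of one synapse over a known spike train.

    ``S_pre[k]`` is the strength immediately before spike k (after
    recovery since the previous event) and ``S_post[k] = f * S_pre[k]``
    immediately after.  ``S_at`` evaluates the trajectory at arbitrary
    times via the closed-form recovery from the last preceding event.
    """

    spike_times: np.ndarray
    S_pre: np.ndarray
    S_post: np.ndarray
    t_end: float
    S_end: float
    f: float
    tau_S: float
    S0: float = 1.0

    def S_at(self, times) -> np.ndarray:
        """Strength at the given times; at an exact spike time the value
        just *before* that spike is reported."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.spike_times, times, side="left")
        out = np.empty_like(times)
        for n, (t, k) in enumerate(zip(times, idx)):
            if k == 0:
                out[n] = recover(self.S0, t, self.tau_S)
            else:
                out[n] = recover(
                    self.S_post[k - 1], t - self.spike_times[k - 1], self.tau_S
                )
        return out


def evolve_train(
    spike_times,
    f: float,
    tau_S: float,
    S0: float = 1.0,
    t_end: float | None = None,
) -> TrainTrajectory:
    """Event-driven exact evolution of S over a sorted spike train.

    Spikes deplete with the convention that the reported pre-spike
    strength is the one released at the spike (depletion applies
    immediately after).
    """
    t = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    if t_end is None:
        t_end = float(t[-1]) if t.size else 0.0
    if t.size and t[-1] > t_end:
        raise ValueError("spike times must not exceed t_end")

    S_pre = np.empty(t.size)
    S_post = np.empty(t.size)
    S = float(S0)
    prev = 0.0
    for k, tk in enumerate(t):
        S = recover(S, tk - prev, tau_S)
        S_pre[k] = S
        S = f * S
        S_post[k] = S
        prev = tk
    S_end = recover(S, t_end - prev, tau_S)
    return TrainTrajectory(t, S_pre, S_post, float(t_end), float(S_end), f, tau_S, S0)


def fit_depression_params(
    spike_times,
    S_pre,
    f0: float = 0.5,
    tau0: float = 100.0,
    S0: float = 1.0,
) -> tuple[float, float]:
    """Recover (f, tau_S) from pre-spike strengths of a known train.

    Least-squares fit of the one-step recurrence
    ``S_pre[k+1] = 1 - (1 - f S_pre[k]) exp(-dt_k / tau_S)`` to the
    observed sequence; requires at least three spikes.
    """
    t = np.asarray(spike_times, dtype=float)
    S = np.asarray(S_pre, dtype=float)
    if t.size < 3:
        raise ValueError("need at least three spikes to fit (f, tau_S)")
    dt = np.diff(t)

    def residual(theta):
        f, tau = theta
        pred = 1.0 - (1.0 - f * S[:-1]) * np.exp(-dt / tau)
        return pred - S[1:]

    sol = least_squares(
        residual,
        x0=[f0, tau0],
        bounds=([1e-6, 1e-3], [1.0 - 1e-9, 1e5]),
    )
    f_hat, tau_hat = sol.x
    return float(f_hat), float(tau_hat)
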