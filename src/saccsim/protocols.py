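"""Stimulus and microsaccade schedules.

A :class:`Protocol` bundles the time course of the fixated-dot position
``x_f(t)`` (driven by a list of microsaccade events) with the stimulus
brightness ``A(t)`` (constant, or a periodic on/off flash cycle).
Microsaccades are displacements of magnitude ``Delta_M``; by default the
displacement is instantaneous, while in velocity mode the dot moves
linearly over a fixed 15 ms saccade duration, matching the roughly
constant microsaccade duration observed in humans.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .network import wrap_position

__all__ = [
    "MicrosaccadeEvent",
    "Protocol",
    "stationary_protocol",
    "flashing_protocol",
    "single_saccade",
    "periodic_saccades",
    "poisson_saccades",
]

SACCADE_DURATION_MS = 15.0  # fixed duration used in finite-velocity mode


@dataclass(frozen=True)
class MicrosaccadeEvent:
    """One microsaccade: onset (ms), magnitude (position units),
    direction (+1/-1) and duration (ms; 0 = instantaneous jump)."""

    onset: float
    magnitude: float
    direction: int = 1
    duration: float = 0.0

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")
        if self.duration < 0:
            raise ValueError("duration must be nonnegative")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class Protocol:
    """Stimulus brightness and fixation trajectory over one run.

    ``segments`` is a piecewise-constant brightness as a list of
    ``(t_start, t_stop, A)`` triples covering [0, duration);
    ``flash_onsets`` lists the start of every on-phase (a stationary
    stimulus has the single onset t = 0).
    """

    duration: float
    segments: list = field(default_factory=list)
    events: list = field(default_factory=list)
    flash_onsets: list = field(default_factory=list)
    x0: float = 0.0

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.onset)
        for ev in self.events:
            if not (0 <= ev.onset < self.duration):
                raise ValueError("event onset outside protocol duration")
        for a, b in zip(self.events, self.events[1:]):
            if a.onset + a.duration > b.onset:
                raise ValueError("overlapping microsaccade events")

    # -- continuous views ---------------------------------------------

    def brightness_at(self, t: float) -> float:
        for t0, t1, A in self.segments:
            if t0 <= t < t1:
                return A
        return 0.0

    def with_events(self, events) -> "Protocol":
        return Protocol(
            self.duration, list(self.segments), list(events),
            list(self.flash_onsets), self.x0,
        )

    # -- discretisation for the simulator -----------------------------

    def step_arrays(self, dt: float, L: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-step fixation position and brightness on the dt grid.

        The position path is piecewise-constant for instantaneous
        events and continuous piecewise-linear during finite-duration
        events; every point is wrapped into [-L, L).
        """
        n = int(round(self.duration / dt))
        if abs(n * dt - self.duration) > 1e-9:
            raise ValueError("protocol duration must be a multiple of dt")
        A = np.zeros(n)
        for t0, t1, amp in self.segments:
            k0 = int(round(t0 / dt))
            k1 = min(int(round(t1 / dt)), n)
            A[k0:k1] = amp
        xf = np.full(n, wrap_position(self.x0, L))
        x = self.x0
        for ev in self.events:
            k0 = int(round(ev.onset / dt))
            x_new = x + ev.direction * ev.magnitude
            if ev.duration == 0:
                xf[k0:] = wrap_position(x_new, L)
            else:
                kd = max(int(round(ev.duration / dt)), 1)
                ramp = x + (x_new - x) * np.arange(1, kd + 1) / kd
                k1 = min(k0 + kd, n)
                xf[k0:k1] = wrap_position(ramp[: k1 - k0], L)
                xf[k1:] = wrap_position(x_new, L)
            x = x_new
        return xf, A

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "segments": [list(s) for s in self.segments],
            "events": [asdict(e) for e in self.events],
            "flash_onsets": list(self.flash_onsets),
            "x0": self.x0,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Protocol":
        return cls(
            duration=data["duration"],
            segments=[tuple(s) for s in data["segments"]],
            events=[MicrosaccadeEvent(**e) for e in data["events"]],
            flash_onsets=list(data["flash_onsets"]),
            x0=data.get("x0", 0.0),
        )

    def save(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "Protocol":
        return cls.from_dict(json.loads(pathlib.Path(path).read_text()))


# -- builders ---------------------------------------------------------


def stationary_protocol(duration: float, A: float) -> Protocol:
    """Constant brightness A, dot fixed at 0, no events."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return Protocol(duration, [(0.0, duration, A)], [], [0.0])


def flashing_protocol(T_on: float, T_off: float, duration: float, A: float) -> Protocol:
    """Brightness cycles A for T_on then 0 for T_off, starting on at t=0.

    T_off = 0 degenerates to the stationary stimulus.
    """
    if T_on <= 0 or T_off < 0:
        raise ValueError("require T_on > 0 and T_off >= 0")
    if T_off == 0:
        return stationary_protocol(duration, A)
    segments, onsets = [], []
    t = 0.0
    while t < duration:
        segments.append((t, min(t + T_on, duration), A))
        onsets.append(t)
        t += T_on + T_off
    return Protocol(duration, segments, [], onsets)


def single_saccade(t_m: float, delta_M: float, direction: int = 1) -> list:
    """One instantaneous displacement of magnitude delta_M at t_m."""
    if t_m < 0:
        raise ValueError("t_m must be nonnegative")
    return [MicrosaccadeEvent(t_m, delta_M, direction)]


def _directions(n: int, policy: str, rng) -> np.ndarray:
    if policy == "random":
        if rng is None:
            raise ValueError("direction policy 'random' needs an rng")
        return rng.choice([-1, 1], size=n)
    if policy == "fixed":
        return np.ones(n, dtype=int)
    if policy == "alternating":
        return np.where(np.arange(n) % 2 == 0, 1, -1)
    raise ValueError(f"unknown direction policy {policy!r}")


def periodic_saccades(
    F: float,
    delta_M: float,
    duration: float,
    start: float = 0.0,
    direction_policy: str = "random",
    rng: np.random.Generator | None = None,
    saccade_duration: float = 0.0,
) -> list:
    """Events at regular intervals 1000/F ms from ``start`` (F in Hz)."""
    if F <= 0:
        raise ValueError("F must be positive")
    onsets = np.arange(start, duration, 1000.0 / F)
    dirs = _directions(onsets.size, direction_policy, rng)
    return [
        MicrosaccadeEvent(float(t), delta_M, int(d), saccade_duration)
        for t, d in zip(onsets, dirs)
    ]


def poisson_saccades(
    F: float,
    delta_M: float,
    duration: float,
    rng: np.random.Generator,
    start: float = 0.0,
    direction_policy: str = "random",
    saccade_duration: float = 0.0,
) -> list:
    """Homogeneous Poisson event train at rate F Hz on [start, duration).

    The train is truncated, not conditioned: no minimum inter-event
    interval is imposed (overlap is avoided in practice by using a low
    rate, e.g. 1.5 Hz, rather than refractoriness).
    """
    if F <= 0:
        raise ValueError("F must be positive")
    onsets = []
    t = start
    while True:
        t += rng.exponential(1000.0 / F)
        if t >= duration:
            break
        onsets.append(t)
    dirs = _directions(len(onsets), direction_policy, rng)
    events = [
        MicrosaccadeEvent(float(t), delta_M, int(d), saccade_duration)
        for t, d in zip(onsets, dirs)
    ]
    if saccade_duration > 0:  # drop events overlapping the previous ramp
        kept = []
        for ev in events:
            if not kept or kept[-1].onset + kept[-1].duration <= ev.onset:
                kept.append(ev)
        events = kept
    return events
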