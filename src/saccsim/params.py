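"""Model parameters and configuration loading.

All times are in milliseconds, rates in spikes/s, voltages in mV, and
positions in the abstract retinotopic units of the ring coordinate
``[-L, L]``.  Defaults are the reference parameter set of the
thalamocortical feedforward model: membrane time constant 30 ms, resting
potential -70 mV, excitatory reversal 0 mV, threshold -55 mV, reset
-58 mV, depression ratio f = 0.75, recovery time constant 200 ms, and a
ring of N = 1000 neurons per layer spanning [-10, 10].
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass

import yaml

__all__ = ["ModelParameters", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class ModelParameters:
    """Scalar constants of the network, membrane and synapse dynamics.

    Parameters
    ----------
    N : int
        Neurons per layer (LGN and V1 share the grid).
    L : float
        Half-width of the ring coordinate; receptive-field centers span
        ``[-L, L]``.
    g : float
        Maximal synaptic conductance (dimensionless jump scale).
    A : float
        Peak input rate at the fixated position, spikes/s.
    sigma1, sigma2 : float
        Widths of the Gaussian input-rate profile and of the Gaussian
        connection-weight profile, in position units.
    f : float
        Multiplicative depletion ratio per presynaptic spike, in (0, 1).
    tau_S : float
        Synaptic recovery time constant, ms.
    tau_m : float
        Membrane time constant, ms.
    V0, VE, V_th, V_reset : float
        Resting, excitatory-reversal, threshold and reset potentials, mV.
    dt : float
        Integration step, ms.
    T_bin : float
        Width of the moving response bin, ms.
    """

    N: int = 1000
    L: float = 10.0
    g: float = 0.15
    A: float = 50.0
    sigma1: float = 1.5
    sigma2: float = 1.5
    f: float = 0.75
    tau_S: float = 200.0
    tau_m: float = 30.0
    V0: float = -70.0
    VE: float = 0.0
    V_th: float = -55.0
    V_reset: float = -58.0
    dt: float = 0.1
    T_bin: float = 50.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigurationError("N must be >= 2")
        if self.L <= 0:
            raise ConfigurationError("L must be positive")
        if not (0.0 < self.f < 1.0):
            raise ConfigurationError("f must lie strictly in (0, 1)")
        for name in ("tau_S", "tau_m", "dt", "sigma1", "sigma2", "T_bin"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.A < 0:
            raise ConfigurationError("A must be nonnegative")
        if self.g < 0:
            raise ConfigurationError("g must be nonnegative")
        if not (self.V0 < self.V_reset < self.V_th < self.VE):
            raise ConfigurationError(
                "voltage ordering V0 < V_reset < V_th < VE violated"
            )
        # Bernoulli thinning of the Poisson input needs R*dt well below 1.
        if self.A * self.dt * 1e-3 >= 0.1:
            raise ConfigurationError(
                "dt too large for peak rate A: require A*dt < 0.1 spikes/step"
            )

    # -- construction -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        """Build from a mapping; unknown keys are rejected by name."""
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "ModelParameters":
        """Load from YAML or JSON; missing keys keep their defaults."""
        text = pathlib.Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    # -- export -------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)
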