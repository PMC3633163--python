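"""Derived RNG streams.

One user-facing seed fans out into independent streams keyed by purpose
(saccade-train generation vs. input spiking) and by sweep coordinates,
so that adding recording or reordering sweep points never perturbs any
individual run.
"""

from __future__ import annotations

import numpy as np


def child_seed(*keys: int) -> int:
    """Deterministic sub-seed (< 2**31) from a tuple of integer keys."""
    ss = np.random.SeedSequence([int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in keys]))
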