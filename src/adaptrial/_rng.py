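"""Deterministic derivation of random substreams.

All randomness in the package flows from one integer master seed.
Independent substreams are derived through :class:`numpy.random.SeedSequence`
spawn keys, so per-trial streams depend only on the master seed and the
trial's index — never on execution order, chunking or worker count.
"""

from __future__ import annotations

import numpy as np


def seed_sequence(entropy, *key: int) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``key`` under ``entropy``."""
    return np.random.SeedSequence(entropy=entropy, spawn_key=tuple(int(k) for k in key))


def substream(entropy, *key: int) -> np.random.Generator:
    """A fresh PCG64 generator for the addressed substream."""
    return np.random.default_rng(seed_sequence(entropy, *key))
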