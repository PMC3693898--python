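"""Keyed random substreams.

Every stochastic operation in the package draws from a substream keyed by a
stable label (and optional integer indices) under one master seed.  Results
are therefore reproducible and independent of the order in which operations
happen to run -- in particular, partitioning work across workers cannot
change the output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]

_MOD = 2**31


def _key_ints(keys: tuple) -> tuple[int, ...]:
    out = []
    for k in keys:
        if isinstance(k, str):
            out.append(zlib.crc32(k.encode("utf-8")))
        elif isinstance(k, (int, np.integer)):
            out.append(int(k) % (2**32))
        else:
            raise TypeError(f"substream keys must be str or int, got {type(k)!r}")
    return tuple(out)


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    The same (master_seed, keys) always yields the same stream; distinct key
    tuples yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key_ints(keys))
    return np.random.default_rng(ss)


def spawn_seed(master_seed: int, *keys) -> int:
    """Derive a small (< 2^31) integer seed for the keyed substream."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key_ints(keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % _MOD)
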