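"""Shared helpers: deterministic seed derivation."""

from __future__ import annotations

import numpy as np


def rng_from(seed: int, *tags: int) -> np.random.Generator:
    """Generator derived from a root seed plus integer tags.

    Distinct tags give independent streams; the same (seed, tags) pair always
    gives the same stream.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(t) for t in tags))
    return np.random.default_rng(ss)


def derive_seed(seed: int, tag: int) -> int:
    """A scalar sub-seed below 2**31, deterministic in (seed, tag)."""
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(tag),)).generate_state(1)[0] % (2**31))
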