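"""Small shared numeric helpers: deterministic rounding and seeding."""

from __future__ import annotations

import zlib
from typing import Union

import numpy as np

__all__ = ["round_half_up", "substream"]


def round_half_up(x: Union[float, np.ndarray], decimals: int = 0):
    """Round with ties away from zero toward +inf (ActiLife-style).

    ``numpy.round`` rounds half to even; count exports and the printed
    tables use half-up, so the pipeline standardizes on it.
    """
    factor = 10.0 ** decimals
    return np.floor(np.asarray(x, dtype=np.float64) * factor + 0.5) / factor


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a single master seed.

    Every stochastic stage draws from ``substream(seed, stage_name)``,
    so stages are individually reproducible and mutually independent.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(int(master_seed) & 0x7FFFFFFF, spawn_key=(key,)))
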