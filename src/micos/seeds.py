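"""Run-level seed registry.

A single top-level seed deterministically derives independent child seeds
for every named stochastic component, so two runs with the same top seed
are byte-for-byte identical on CPU while components never share streams.
"""

from __future__ import annotations

import zlib

import numpy as np


class SeedRegistry:
    """Derives stable per-component integer seeds from one run seed."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._cache: dict[str, int] = {}

    def get(self, name: str) -> int:
        """Child seed for *name* (stable across calls and runs; < 2**31)."""
        if name not in self._cache:
            h = np.random.SeedSequence(
                [self.seed, zlib.crc32(name.encode())]).generate_state(1)[0]
            self._cache[name] = int(h % (2**31))
        return self._cache[name]

    def rng(self, name: str) -> np.random.Generator:
        return np.random.default_rng(self.get(name))
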