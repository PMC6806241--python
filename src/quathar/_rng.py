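"""Seed plumbing: every stochastic stage derives its generator from a single
root seed plus a named path, so any intermediate artifact is replayable."""

from __future__ import annotations

import zlib

import numpy as np


def substream(root_seed: int, *path: str | int) -> np.random.Generator:
    """Independent, reproducible generator for a named substream.

    The root seed and a stable hash of each path element are folded into a
    :class:`numpy.random.SeedSequence`, so substreams are decorrelated and
    insensitive to the order in which other substreams are drawn.
    """
    entropy = [int(root_seed) & 0x7FFFFFFF]
    for p in path:
        if isinstance(p, str):
            entropy.append(zlib.crc32(p.encode()))
        else:
            entropy.append(int(p) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))
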