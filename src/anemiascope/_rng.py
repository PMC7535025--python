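"""Named random substreams.

Every stochastic stage draws from its own substream derived from the single
top-level seed plus a stable name, so adding or reordering stages never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator keyed by (seed, name), stable across runs and platforms."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
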