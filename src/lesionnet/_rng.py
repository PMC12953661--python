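"""Named random substreams.

A master seed spawns an independent, reproducible stream per generator name,
so adding a new generator never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name).

    The name is hashed with CRC-32 (stable across processes and Python
    versions, unlike ``hash``) and folded into the seed sequence entropy.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
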