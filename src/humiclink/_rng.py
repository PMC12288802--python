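"""Named RNG substreams derived from a single root seed.

Every stochastic stage of the package derives its generator as
``substream(seed, "stage-name")`` so that stages are independently
reproducible: changing the number of draws in one stage never perturbs
another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from root ``seed``.

    The stage name is hashed with CRC32 into the SeedSequence spawn key, so
    identical (seed, name) pairs always yield identical streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
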