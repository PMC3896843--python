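"""Named, reproducible random substreams.

Every source of randomness in the package flows from one root seed through
`substream(seed, *labels)`, so any component can be regenerated in isolation
and two runs with the same (config, seed) are bitwise identical.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels``.

    The label sequence is hashed (CRC32, stable across platforms and runs)
    into the SeedSequence spawn key, so distinct label paths give
    independent streams while identical paths reproduce exactly.
    """
    key = tuple(zlib.crc32(str(lab).encode("utf8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
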