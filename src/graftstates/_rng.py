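"""Named, platform-stable random substreams.

All simulation randomness flows from one root seed.  Each generator module
draws from its own named substream so cohorts, spatial fields and bulk
cohorts can be regenerated independently without perturbing each other.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    # sha256, not hash(): must be identical across processes and platforms
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under root ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)
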