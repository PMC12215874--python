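"""Named, independent RNG substreams derived from one root seed.

Every stochastic component draws from its own substream so that adding or
removing draws in one component never shifts the stream seen by another.
Substream identity is the (root seed, name) pair; the name is hashed with a
stable digest so streams are reproducible across processes and platforms.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))
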