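"""Named random substreams.

All randomness in the package flows from one root seed.  Each stage draws
from a named substream so that adding a stage, or reordering stages, never
perturbs the draws of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_entropy(name: str) -> int:
    return int.from_bytes(hashlib.blake2s(name.encode(), digest_size=4).digest(), "big")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_entropy(name)]))


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for the substream ``name``."""
    ss = np.random.SeedSequence([int(seed), _name_entropy(name)])
    return int(ss.generate_state(1)[0] % (2**31))
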