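"""Deterministic seed derivation for nested experiment loops.

Every stochastic component derives its own ``numpy.random.SeedSequence`` from
a root seed plus a content key (tissue values, scheme angles, bound values,
realization index ...).  Two calls that describe the same computation thus
receive bitwise-identical random streams regardless of the order, grouping or
parallel scheduling in which the work is executed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed_sequence", "derive_rng"]


def _key_words(labels) -> list[int]:
    digest = hashlib.blake2s(repr(labels).encode("utf-8")).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def derive_seed_sequence(root_seed: int, *labels) -> np.random.SeedSequence:
    """SeedSequence keyed by the root seed and a stable hash of the labels."""
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, *_key_words(labels)])


def derive_rng(root_seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(derive_seed_sequence(root_seed, *labels))
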