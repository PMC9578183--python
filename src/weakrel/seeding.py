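"""Deterministic child-seed derivation.

Every stage draws its randomness from a seed derived by hashing the global
seed together with a stage-specific token path, so any sub-grid of an
experiment is reproducible in isolation.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31


def child_seed(seed: int, *tokens) -> int:
    """Derive a sub-seed < 2**31 from ``seed`` and a token path.

    Stable across processes and platforms (unlike builtin ``hash``).
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(repr(int(seed)).encode())
    for tok in tokens:
        h.update(b"|")
        h.update(repr(tok).encode())
    return int.from_bytes(h.digest(), "big") % _MOD


def unit_uniform(seed: int, *tokens) -> float:
    """A deterministic uniform in [0, 1) keyed by ``seed`` and tokens."""
    h = hashlib.blake2b(digest_size=8)
    h.update(repr(int(seed)).encode())
    for tok in tokens:
        h.update(b"|")
        h.update(repr(tok).encode())
    return int.from_bytes(h.digest(), "big") / 2**64
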