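"""Deterministic sub-seed derivation.

A single master seed fans out to every randomised stage (pseudo-absence
realizations, train/test splits, learner initialisation, importance
shuffles) through a stable hash of ``(master, stage, *indices)``, so
stages are mutually independent yet the whole pipeline is reproducible
from one integer.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *parts) -> int:
    """Derive a 31-bit sub-seed from a master seed and a label path."""
    key = ":".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
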