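"""Small shared helpers: deterministic seed derivation and label coding."""

from __future__ import annotations

import hashlib

import numpy as np

EC = "EC"
NON_EC = "NonEC"


def derive_seed(master: int, *tags) -> int:
    """Derive a child seed (< 2**31) from a master seed and a tag tuple.

    Stable across processes and Python versions (blake2s, not ``hash``), so a
    single master seed fans out to reproducible per-stage / per-repeat seeds.
    """
    payload = repr((int(master),) + tuple(tags)).encode()
    digest = hashlib.blake2s(payload, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def binary_labels(groups, positive: str = EC) -> np.ndarray:
    """Map group labels to 0/1 with ``positive`` coded 1."""
    groups = np.asarray(groups)
    return (groups == positive).astype(int)
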