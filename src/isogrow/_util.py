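"""Small shared helpers: sequence ops and seed substreams."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def substream_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a global seed.

    Stage-level reproducibility must not depend on the order stages run in,
    so each stage hashes its own name against the global seed.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, stage))


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= DNA_ALPHABET
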