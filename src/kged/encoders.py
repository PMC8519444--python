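"""Text encoders for entity and relation descriptions.

The description branch of the scoring model consumes a fixed-length vector
per description.  Any callable satisfying :class:`TextEncoder` can supply
these vectors; the default :class:`HashingTextEncoder` is a deterministic,
dependency-free feature-hashing encoder so the whole pipeline runs offline.
An adapter around a pre-trained sentence encoder (which produces
512-dimensional vectors) can be plugged in wherever an encoder is accepted.
"""

from __future__ import annotations

import hashlib
import re
from typing import Protocol, runtime_checkable

import numpy as np

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@runtime_checkable
class TextEncoder(Protocol):
    """Contract: map text to an ``dim``-length vector, reproducibly."""

    dim: int
    deterministic: bool

    def encode(self, text: str) -> np.ndarray: ...


class HashingTextEncoder:
    """Deterministic feature-hashing sentence encoder.

    Lower-cased word unigrams and bigrams are hashed (BLAKE2, stable across
    processes) into ``dim`` buckets with a signed contribution, and the
    resulting vector is L2-normalized.  Texts sharing tokens therefore map to
    nearby unit vectors, which is all the description branch needs: a fixed,
    frozen embedding whose geometry reflects lexical overlap.
    """

    deterministic = True

    def __init__(self, dim: int = 512):
        if dim < 1:
            raise ValueError("encoder dimension must be positive")
        self.dim = dim

    def _hash(self, token: str) -> tuple[int, float]:
        h = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
        v = int.from_bytes(h, "big")
        return v % self.dim, 1.0 if (v >> 63) & 1 else -1.0

    def encode(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        tokens = _TOKEN_RE.findall(text.lower())
        grams = tokens + [f"{a}_{b}" for a, b in zip(tokens, tokens[1:])]
        for g in grams:
            idx, sign = self._hash(g)
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec
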