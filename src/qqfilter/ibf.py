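"""Bloom filter mathematics and the interleaved Bloom filter (IBF).

An IBF with ``b`` bins interleaves ``b`` Bloom filters of ``n`` bits each:
bit ``j`` of sub-vector ``i`` (absolute bit ``i*b + j``) belongs to bin
(experiment) ``j``.  A membership query hashes the value with ``h`` seeded
hash functions, gathers the ``h`` addressed b-bit sub-vectors and ANDs them
into one b-bit answer -- one lookup reports the value's presence in every
experiment at once.  Bloom filters admit false positives but never false
negatives.
"""

from __future__ import annotations

import io
import math
import struct
from dataclasses import dataclass

import numpy as np

from ._hash import HASH_SEEDS, hash_positions

_MAGIC = b"QQFIBF01"


@dataclass(frozen=True)
class BloomSpec:
    """Per-bin Bloom geometry: bits ``n``, hash count ``h``, pinned seeds."""

    n: int
    h: int = 3
    hash_seeds: tuple[int, ...] = HASH_SEEDS[:3]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if len(self.hash_seeds) != self.h:
            raise ValueError("need exactly h hash seeds")
        if len(set(self.hash_seeds)) != self.h:
            raise ValueError("hash seeds must be pairwise distinct")


def false_positive_rate(n: int, m: float, h: int) -> float:
    """Probability that a Bloom filter of ``n`` bits holding ``m`` elements
    answers present for an absent value: ``(1 - (1 - 1/n)**(h*m))**h``."""
    if n < 1 or m < 0 or h < 1:
        raise ValueError("require n >= 1, m >= 0, h >= 1")
    if m == 0:
        return 0.0
    return (1.0 - (1.0 - 1.0 / n) ** (h * m)) ** h


def size_for_fpr(m: float, h: int, p: float) -> int:
    """Smallest ``n`` with ``false_positive_rate(n, m, h) <= p``.

    Inverts the false-positive formula analytically, then nudges ``n`` so the
    bound holds exactly.  ``m`` may be fractional (an average load).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"target false positive rate must be in (0, 1), got {p}")
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return 1
    # n = 1 / (1 - (1 - p^(1/h))^(1/(h m)))
    base = 1.0 - p ** (1.0 / h)
    denom = 1.0 - base ** (1.0 / (h * m))
    n = max(1, math.ceil(1.0 / denom)) if denom > 0 else 1
    while false_positive_rate(n, m, h) > p:
        n += 1
    while n > 1 and false_positive_rate(n - 1, m, h) <= p:
        n -= 1
    return n


class InterleavedBloomFilter:
    """``b`` interleaved Bloom filters sharing one :class:`BloomSpec`.

    Stored internally as a ``(n, b)`` boolean matrix: row ``i`` is the i-th
    b-bit sub-vector.  Serialized little-endian bit-packed with bit ``j`` of
    sub-vector ``i`` at absolute bit ``i*b + j``.
    """

    def __init__(self, b: int, spec: BloomSpec) -> None:
        if b < 1:
            raise ValueError("b must be >= 1")
        self.b = b
        self.spec = spec
        self.bits = np.zeros((spec.n, b), dtype=bool)

    def _positions(self, values) -> np.ndarray:
        return hash_positions(
            np.atleast_1d(np.asarray(values, dtype=np.uint64)),
            self.spec.n,
            self.spec.hash_seeds,
        )

    def insert(self, value: int, bin_: int) -> None:
        """Set bin ``bin_`` in the ``h`` sub-vectors addressed by ``value``."""
        self.insert_many([value], bin_)

    def insert_many(self, values, bin_: int) -> None:
        if not 0 <= bin_ < self.b:
            raise IndexError(f"bin {bin_} out of range [0, {self.b})")
        values = np.asarray(values, dtype=np.uint64)
        if values.size == 0:
            return
        pos = self._positions(values)
        self.bits[pos.ravel(), bin_] = True

    def membership(self, value: int) -> np.ndarray:
        """b-bit membership vector: AND over the ``h`` addressed sub-vectors."""
        pos = self._positions([value])[0]
        return np.logical_and.reduce(self.bits[pos], axis=0)

    def bulk_counts(self, values) -> np.ndarray:
        """Element-wise sum of membership vectors over ``values``.

        List semantics: a duplicated query value is counted once per
        occurrence.  Returns an integer vector of length ``b``.
        """
        values = np.asarray(values, dtype=np.uint64)
        if values.size == 0:
            return np.zeros(self.b, dtype=np.int64)
        pos = self._positions(values)  # (len, h)
        hits = np.logical_and.reduce(self.bits[pos], axis=1)  # (len, b)
        return hits.sum(axis=0).astype(np.int64)

    # -- serialization ----------------------------------------------------

    def to_bytes(self) -> bytes:
        header = _MAGIC + struct.pack(
            "<QQQB", self.b, self.spec.n, self.spec.h, 0  # flag byte: uncompressed
        )
        header += struct.pack(f"<{self.spec.h}Q", *self.spec.hash_seeds)
        packed = np.packbits(self.bits.ravel(), bitorder="little")
        return header + packed.tobytes()

    @classmethod
    def from_bytes(cls, blob: bytes) -> "InterleavedBloomFilter":
        buf = io.BytesIO(blob)
        magic = buf.read(8)
        if magic != _MAGIC:
            raise ValueError(
                f"bad IBF magic {magic!r}; expected {_MAGIC.decode()} "
                "(file truncated or not an IBF blob)"
            )
        b, n, h, flag = struct.unpack("<QQQB", buf.read(25))
        if flag != 0:
            raise ValueError("compressed IBF blobs are not supported")
        seeds = struct.unpack(f"<{h}Q", buf.read(8 * h))
        nbits = b * n
        payload = buf.read()
        if len(payload) != (nbits + 7) // 8:
            raise ValueError("IBF blob truncated: bitvector payload incomplete")
        ibf = cls(int(b), BloomSpec(n=int(n), h=int(h), hash_seeds=tuple(seeds)))
        bits = np.unpackbits(
            np.frombuffer(payload, dtype=np.uint8), bitorder="little"
        )[:nbits]
        ibf.bits = bits.astype(bool).reshape(int(n), int(b))
        return ibf

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InterleavedBloomFilter):
            return NotImplemented
        return (
            self.b == other.b
            and self.spec == other.spec
            and bool(np.array_equal(self.bits, other.bits))
        )
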