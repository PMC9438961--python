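"""64-bit mixing and fastrange reduction used by the Bloom filters.

The Bloom filter layer needs ``h`` independent, uniform hash functions of a
64-bit minimizer value.  Each is the splitmix64 finalizer applied to the value
XOR a fixed seed, followed by a multiply-shift ("fastrange") reduction onto
``[0, n)``.  The seeds are the fractional bits of the square roots of the
first primes -- large irrational constants, pinned here so that indexes are
reproducible across machines.
"""

from __future__ import annotations

import numpy as np

MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)

# Fractional parts of sqrt(2), sqrt(3), sqrt(5), ... scaled to 64 bits.
HASH_SEEDS: tuple[int, ...] = (
    0x6A09E667F3BCC908,
    0xBB67AE8584CAA73B,
    0x3C6EF372FE94F82B,
    0xA54FF53A5F1D36F1,
    0x510E527FADE682D1,
    0x9B05688C2B3E6C1F,
    0x1F83D9ABFB41BD6B,
    0x5BE0CD19137E2179,
)

_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """splitmix64 finalizer of ``x ^ seed`` (vectorized, uint64)."""
    with np.errstate(over="ignore"):
        z = (np.asarray(x, dtype=np.uint64) ^ np.uint64(seed)) + _GOLDEN
        z = (z ^ (z >> np.uint64(30))) * _C1
        z = (z ^ (z >> np.uint64(27))) * _C2
        return z ^ (z >> np.uint64(31))


def fastrange(x: np.ndarray, n: int) -> np.ndarray:
    """Map uint64 hashes onto ``[0, n)`` via floor(x*n / 2**64).

    Exact for ``n < 2**32`` (a single IBF level never needs more sub-vectors
    than that at the problem sizes this package targets).
    """
    if n >= 1 << 32:  # pragma: no cover - guard
        raise ValueError("fastrange reduction supports n < 2**32")
    x = np.asarray(x, dtype=np.uint64)
    nn = np.uint64(n)
    with np.errstate(over="ignore"):
        hi = x >> np.uint64(32)
        lo = x & np.uint64(0xFFFFFFFF)
        s = hi * nn + ((lo * nn) >> np.uint64(32))
        return s >> np.uint64(32)


def hash_positions(values: np.ndarray, n: int, seeds: tuple[int, ...]) -> np.ndarray:
    """Positions array of shape ``(len(values), len(seeds))`` in ``[0, n)``."""
    values = np.asarray(values, dtype=np.uint64)
    out = np.empty((values.size, len(seeds)), dtype=np.int64)
    for j, seed in enumerate(seeds):
        out[:, j] = fastrange(mix64(values, seed), n).astype(np.int64)
    return out
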