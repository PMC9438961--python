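"""Canonical (w,k)-minimizer extraction and per-experiment minimizer counting.

A (w,k)-minimizer is the smallest k-mer -- over both strands, under a
randomized order -- inside a window of ``w`` consecutive bases.  Consecutive
windows that share their minimizer contribute a single *run*, so a sequence of
length ``L`` yields at most ``L - w + 1`` minimizers and usually far fewer.
With ``w == k`` the minimizers are exactly the canonical k-mers.

k-mers are encoded in 2 bits per base (A=0, C=1, G=2, T=3, leftmost base in
the most significant bits), so any ``k <= 32`` fits one 64-bit word.  The
ordering used to pick the window minimum is the encoding XOR a fixed 64-bit
mask (``order_seed``); randomizing the order this way avoids the skew of plain
lexicographic minimizers while staying order-isomorphic and reproducible.

Windows overlapping an ambiguous base (anything outside ACGT) yield no
minimizer.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Default XOR mask for the minimizer ordering (2**64 / golden ratio).
DEFAULT_ORDER_SEED = 0x9E3779B97F4A7C15

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a base outside A/C/G/T.

    Callers extracting minimizers do not see this: windows containing an
    ambiguous base are silently skipped.
    """


@dataclass(frozen=True)
class MinimizerParams:
    """Sketching parameters: k-mer size, window size and ordering seed.

    Invariants: ``1 <= k <= 32`` and ``w >= k``.  Identical params applied to
    a sequence and to its reverse complement yield the same minimizer
    multiset.
    """

    k: int = 21
    w: int = 25
    order_seed: int = DEFAULT_ORDER_SEED

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if self.w < self.k:
            raise ValueError(f"window w={self.w} must be >= k={self.k}")

    @property
    def _order_mask(self) -> int:
        return self.order_seed & ((1 << (2 * self.k)) - 1)


@dataclass(frozen=True)
class MinimizerRun:
    """One run of consecutive windows sharing a minimizer value.

    ``start`` is the 0-based index of the first window of the run.
    """

    value: int
    start: int


@dataclass
class ExperimentCounts:
    """Minimizer -> occurrence count over all reads of one experiment."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_minimizers(self) -> int:
        return sum(self.counts.values())


def encode_kmer(kmer: str) -> int:
    """2-bit encode a k-mer, most significant bits = leftmost base."""
    code = 0
    for ch in kmer:
        b = _BASE_CODE[ord(ch)]
        if b == 255:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in k-mer {kmer!r}")
        code = (code << 2) | int(b)
    return code


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def canonical_kmer(kmer: str, params: MinimizerParams) -> int:
    """Encoded canonical form of ``kmer``: the strand whose encoding is
    smaller under XOR with the ordering seed.

    Raises :class:`AmbiguousBaseError` for non-ACGT bases (the caller is
    expected to drop every window containing such a base).
    """
    if len(kmer) != params.k:
        raise ValueError(f"k-mer length {len(kmer)} != k={params.k}")
    fwd = encode_kmer(kmer)
    rc = encode_kmer(reverse_complement(kmer))
    s = params._order_mask
    return fwd if (fwd ^ s) <= (rc ^ s) else rc


def _encode_sequence(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    return codes, codes != 255


def _canonical_codes(codes: np.ndarray, k: int, order_mask: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-kmer canonical encodings and their XOR-transformed order keys."""
    n = codes.size - k + 1
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            b = codes[j : j + n].astype(np.uint64)
            fwd = (fwd << np.uint64(2)) | b
            rc |= (np.uint64(3) - b) << np.uint64(2 * j)
    s = np.uint64(order_mask)
    tf, tr = fwd ^ s, rc ^ s
    canon = np.where(tf <= tr, fwd, rc)
    return canon, canon ^ s


def minimizers(seq: str, params: MinimizerParams) -> list[MinimizerRun]:
    """Run-compressed (w,k)-minimizers of ``seq``.

    One entry per run of consecutive windows sharing a minimizer value;
    windows overlapping an ambiguous base are skipped; sequences shorter than
    ``w`` yield an empty list.
    """
    k, w = params.k, params.w
    n_windows = len(seq) - w + 1
    if n_windows <= 0:
        return []
    codes, valid = _encode_sequence(seq)
    canon, keys = _canonical_codes(codes, k, params._order_mask)

    # window i is valid iff bases [i, i+w) are all ACGT
    bad = np.concatenate(([0], np.cumsum(~valid)))
    win_valid = (bad[w:] - bad[:-w]) == 0

    kpw = w - k + 1  # k-mers per window
    windows = np.lib.stride_tricks.sliding_window_view(keys, kpw)
    argmin = np.argmin(windows, axis=1)  # leftmost minimum
    win_value = canon[np.arange(n_windows) + argmin]

    idx = np.nonzero(win_valid)[0]
    if idx.size == 0:
        return []
    vals = win_value[idx]
    new_run = np.ones(idx.size, dtype=bool)
    new_run[1:] = (np.diff(idx) != 1) | (np.diff(vals) != 0)
    starts = np.nonzero(new_run)[0]
    return [MinimizerRun(int(vals[s]), int(idx[s])) for s in starts]


def minimizer_values(seq: str, params: MinimizerParams) -> list[int]:
    """Values of the run-compressed minimizer list (multiset, in order)."""
    return [r.value for r in minimizers(seq, params)]


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_sequences(path: str | Path) -> Iterator[str]:
    """Yield sequences from a FASTA or FASTQ file, plain or gzipped.

    The format is sniffed from the first character of the (decompressed)
    stream.  An unparseable file raises :class:`ValueError` naming it; an
    empty file yields nothing and logs a warning.
    """
    path = Path(path)
    try:
        with _open_maybe_gzip(path) as handle:
            first = handle.read(1)
            if first == "":
                logger.warning("input file %s is empty", path)
                return
            handle.seek(0)
            if first == ">":
                fmt = "fasta"
            elif first == "@":
                fmt = "fastq"
            else:
                raise ValueError("not FASTA or FASTQ")
            for record in SeqIO.parse(handle, fmt):
                yield str(record.seq)
    except ValueError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    except OSError as exc:
        raise ValueError(f"cannot read {path}: {exc}") from exc


def count_minimizers(
    files: Sequence[str | Path], params: MinimizerParams
) -> ExperimentCounts:
    """Aggregate minimizer run occurrences over all reads of all ``files``.

    Paired-end mates belong to the same experiment and are simply pooled.
    """
    counter: Counter[int] = Counter()
    for path in files:
        for seq in iter_sequences(path):
            counter.update(minimizer_values(seq, params))
    return ExperimentCounts(counts=dict(counter))
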