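"""Reproducible synthetic transcripts and read sets.

Emulates a bulk RNA-seq differential-expression simulation: random
transcripts stand in for sampled protein-coding transcripts, uniform-coverage
75-bp paired-end reads are drawn from them, a configurable fraction of
transcripts is differentially expressed with fold changes 1/4, 1/2, 2 or 4
(equal probability), and several coverage levels can be generated from the
same expression profile.  Read counts are deterministic given the design
seed: per transcript, ``round(coverage * length / (2 * read_length))`` pairs,
scaled by the fold change for differentially expressed transcripts in the
alternate condition.

No sequencing errors are introduced by default; an optional uniform
substitution rate exists for robustness experiments.  The ground truth table,
not biology, is the oracle for every downstream test.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sketch import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationDesign:
    """Study design for one simulated dataset."""

    n_transcripts: int = 100
    length_range: tuple[int, int] = (500, 3000)
    read_length: int = 75
    paired: bool = True
    coverages: tuple[int, ...] = (20, 40, 60, 80)
    de_fraction: float = 0.1
    fold_changes: tuple[float, ...] = (0.25, 0.5, 2.0, 4.0)
    error_rate: float = 0.0
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if any(c <= 0 for c in self.coverages):
            raise ValueError("coverages must be positive")
        if self.read_length > self.length_range[0]:
            raise ValueError("read_length must not exceed the minimum transcript length")


def _rng(design: SimulationDesign, *tags: str) -> np.random.Generator:
    words = [design.rng_seed & 0x7FFFFFFF]
    words += [zlib.crc32(t.encode()) & 0x7FFFFFFF for t in tags]
    return np.random.default_rng(words)


def simulate_transcripts(design: SimulationDesign) -> list[tuple[str, str]]:
    """Uniform-random ACGT transcripts; ``(id, sequence)`` pairs."""
    rng = _rng(design, "transcripts")
    lo, hi = design.length_range
    out = []
    for i in range(design.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        out.append((f"tx{i:04d}", seq))
    return out


def assign_fold_changes(design: SimulationDesign) -> pd.DataFrame:
    """Ground-truth DE status: which transcripts are differentially
    expressed and at which fold change (1.0 for the rest)."""
    rng = _rng(design, "truth")
    n = design.n_transcripts
    n_de = int(round(design.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    folds = np.ones(n)
    if n_de:
        folds[de_idx] = rng.choice(design.fold_changes, size=n_de)
    return pd.DataFrame(
        {
            "transcript": [f"tx{i:04d}" for i in range(n)],
            "de": np.isin(np.arange(n), de_idx),
            "fold_change": folds,
        }
    ).set_index("transcript")


def expected_pairs(length: int, coverage: float, read_length: int, paired: bool) -> int:
    bases_per_unit = read_length * (2 if paired else 1)
    return int(round(coverage * length / bases_per_unit))


def simulate_reads(
    transcripts: list[tuple[str, str]],
    truth: pd.DataFrame,
    design: SimulationDesign,
    *,
    coverage: float,
    condition: str = "A",
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Uniform-start paired-end reads from every transcript.

    Condition "A" is the baseline; in condition "B" differentially expressed
    transcripts have their read-pair count multiplied by their fold change.
    Returns (mate1, mate2) lists of ``(read_id, sequence)``; mate2 is empty
    for single-end designs.  Deterministic given the design seed.
    """
    if condition not in ("A", "B"):
        raise ValueError("condition must be 'A' or 'B'")
    rng = _rng(design, "reads", condition, f"cov{coverage}")
    rl = design.read_length
    mate1: list[tuple[str, str]] = []
    mate2: list[tuple[str, str]] = []
    for tid, seq in transcripts:
        length = len(seq)
        if rl > length:
            continue
        n_pairs = expected_pairs(length, coverage, rl, design.paired)
        if condition == "B" and bool(truth.loc[tid, "de"]):
            n_pairs = int(round(n_pairs * float(truth.loc[tid, "fold_change"])))
        max_frag = min(2 * rl + 50, length)
        for r in range(n_pairs):
            frag_len = int(rng.integers(rl, max_frag + 1)) if design.paired else rl
            start = int(rng.integers(0, length - frag_len + 1))
            frag = seq[start : start + frag_len]
            fwd = frag[:rl]
            if design.error_rate > 0:
                fwd = _mutate(fwd, design.error_rate, rng)
            name = f"{tid}:{condition}:cov{coverage}:{r}"
            mate1.append((name, fwd))
            if design.paired:
                rev = reverse_complement(frag[-rl:])
                if design.error_rate > 0:
                    rev = _mutate(rev, design.error_rate, rng)
                mate2.append((name, rev))
    return mate1, mate2


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(records: list[tuple[str, str]], path: str | Path) -> None:
    """Plain or gzipped FASTQ (by extension) with uniform high base quality."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


_FIXTURES = ("tiny", "fig4-like", "fc-recovery")


def distinct_canonical_kmer_sequence(
    length: int, k: int, order_seed: int, seed: int
) -> str:
    """Rejection-sample a sequence whose canonical k-mers are pairwise
    distinct (e.g. a 17-nt sequence with 14 distinct canonical 4-mers)."""
    from .sketch import MinimizerParams, minimizer_values

    params = MinimizerParams(k=k, w=k, order_seed=order_seed)
    rng = np.random.default_rng(seed)
    n_kmers = length - k + 1
    for _ in range(100_000):
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        values = minimizer_values(seq, params)
        if len(values) == n_kmers and len(set(values)) == n_kmers:
            return seq
    raise RuntimeError("could not sample a sequence with distinct canonical k-mers")


def make_fixture(name: str, out_dir: str | Path, seed: int = 1) -> dict:
    """Write a named test fixture (FASTA/FASTQ + truth.tsv) and return its
    manifest: file paths per experiment, transcript FASTA and truth table.

    Known fixtures: "tiny" (5 transcripts, 2 experiments), "fig4-like"
    (a 17-nt query with 14 distinct canonical 4-mers plus 3 small
    experiments), "fc-recovery" (20 x 500 nt transcripts, conditions A/B at
    coverages 8 and 16).
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if name == "tiny":
        design = SimulationDesign(
            n_transcripts=5, length_range=(250, 400), read_length=75,
            coverages=(10,), de_fraction=0.2, rng_seed=seed,
        )
        conditions = [("A", 10.0), ("B", 10.0)]
    elif name == "fc-recovery":
        design = SimulationDesign(
            n_transcripts=20, length_range=(500, 500), read_length=75,
            coverages=(8, 16), de_fraction=0.1, rng_seed=seed,
        )
        conditions = [("A", 8.0), ("B", 8.0), ("A", 16.0), ("B", 16.0)]
    else:  # fig4-like
        query = distinct_canonical_kmer_sequence(17, 4, order_seed=0, seed=seed)
        write_fasta([("query17", query)], out / "query.fa")
        design = SimulationDesign(
            n_transcripts=3, length_range=(200, 300), read_length=75,
            coverages=(8,), de_fraction=0.0, rng_seed=seed,
        )
        conditions = [("A", 8.0)]

    transcripts = simulate_transcripts(design)
    truth = assign_fold_changes(design)
    write_fasta(transcripts, out / "transcripts.fa")

    experiments: list[tuple[str, list[str]]] = []
    rows = []
    for condition, coverage in conditions:
        label = f"{condition}_cov{coverage:g}"
        mate1, mate2 = simulate_reads(
            transcripts, truth, design, coverage=coverage, condition=condition
        )
        f1 = out / f"{label}_1.fq.gz"
        write_fastq(mate1, f1)
        files = [str(f1)]
        if design.paired:
            f2 = out / f"{label}_2.fq.gz"
            write_fastq(mate2, f2)
            files.append(str(f2))
        experiments.append((label, files))
        for tid, seq in transcripts:
            n = expected_pairs(len(seq), coverage, design.read_length, design.paired)
            if condition == "B" and bool(truth.loc[tid, "de"]):
                n = int(round(n * float(truth.loc[tid, "fold_change"])))
            rows.append((tid, len(seq), label, n))

    truth_out = truth.reset_index().merge(
        pd.DataFrame(rows, columns=["transcript", "length", "experiment", "read_pairs"]),
        on="transcript",
    )
    truth_out.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest = {
        "design": design,
        "transcripts_fasta": str(out / "transcripts.fa"),
        "experiments": experiments,
        "truth": truth_out,
    }
    if name == "fig4-like":
        manifest["query_fasta"] = str(out / "query.fa")
    return manifest
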