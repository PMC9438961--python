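"""Construction and (de)serialization of the q-quantitative filter index.

The index holds ``q`` interleaved Bloom filters (one per count level), the
per-experiment threshold schemes, and the *actual* per-experiment per-level
false-positive rates.  Each level's IBF is sized from the target
false-positive rate and the *average* per-experiment load at that level, so
an experiment with far more minimizers than average exceeds the target rate
-- which is why the actual rates are stored and used to correct query counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ibf import BloomSpec, InterleavedBloomFilter, false_positive_rate, size_for_fpr
from ._hash import HASH_SEEDS
from .sketch import ExperimentCounts, MinimizerParams, count_minimizers
from .thresholds import ThresholdScheme, auto_thresholds, cutoff_for_file_size, level_of

logger = logging.getLogger(__name__)

INDEX_VERSION = 1
_MIN_BIN_BITS = 64  # floor avoids degenerate all-collision levels


@dataclass
class QQIndex:
    """The serialized artifact: q IBFs + thresholds + actual FPRs.

    ``level_fprs[e][i]`` is the Bloom false-positive rate experiment ``e``
    actually attains at level ``i+1`` given how many minimizers it inserted
    there; ``normalization_divisors`` (auto mode only) holds each
    experiment's second-level threshold ``t_2``.
    """

    params: MinimizerParams
    q: int
    h: int
    target_fpr: float
    ibfs: list[InterleavedBloomFilter]
    experiments: list[str]
    schemes: list[ThresholdScheme]
    level_fprs: np.ndarray  # shape (b, q)
    normalization_divisors: list[int] | None = None
    query_passes: int = field(default=0, compare=False)  # instrumentation

    @property
    def b(self) -> int:
        return len(self.experiments)

    @property
    def mode(self) -> str:
        return self.schemes[0].mode

    def __post_init__(self) -> None:
        if len(self.ibfs) != self.q:
            raise ValueError("need one IBF per level")
        if any(ibf.b != self.b for ibf in self.ibfs):
            raise ValueError("all IBFs must have one bin per experiment")
        if len(self.schemes) != self.b:
            raise ValueError("need one threshold scheme per experiment")


def plan_level_sizes(
    predicted_loads: np.ndarray, h: int, p: float
) -> list[int]:
    """Bits per bin for each level: sized for the mean per-experiment load.

    ``predicted_loads`` has shape (experiments, q).  A level with zero mean
    load gets the minimal 64-bit bin.
    """
    loads = np.atleast_2d(np.asarray(predicted_loads, dtype=float))
    sizes = []
    for i in range(loads.shape[1]):
        mean = float(loads[:, i].mean())
        if mean <= 0:
            logger.warning("level %d has no predicted load; using minimal bins", i + 1)
            sizes.append(_MIN_BIN_BITS)
        else:
            sizes.append(max(_MIN_BIN_BITS, size_for_fpr(mean, h, p)))
    return sizes


def predicted_auto_loads(total_minimizers: int, q: int) -> list[float]:
    """Expected per-level load under automatic thresholds: the total number
    of minimizers halved once per level."""
    return [total_minimizers / 2**i for i in range(1, q + 1)]


def _file_sizes(files: Sequence[str | Path]) -> int:
    return sum(os.path.getsize(f) for f in files)


def build_index(
    experiments: Sequence[tuple[str, Sequence[str | Path]]],
    params: MinimizerParams,
    q: int,
    *,
    mode: str = "auto",
    user_thresholds: Sequence[int] | None = None,
    cutoff: int | str = "auto",
    target_fpr: float = 0.05,
    h: int = 3,
    hash_seeds: Sequence[int] | None = None,
) -> QQIndex:
    """Count each experiment's minimizers, derive thresholds, size the q
    IBFs from the target false-positive rate and insert every surviving
    minimizer at the level its count selects.

    ``cutoff`` is an integer or "auto" (file-size rule on the summed on-disk
    sizes of the experiment's files).  In user mode ``user_thresholds`` is
    one global ascending list of length ``q``.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    names = [name for name, _ in experiments]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate experiment names in {names}")
    if mode not in ("auto", "user"):
        raise ValueError(f"mode must be 'auto' or 'user', got {mode!r}")
    if mode == "user":
        if user_thresholds is None or len(user_thresholds) != q:
            raise ValueError(f"user mode needs exactly q={q} thresholds")
        global_scheme = ThresholdScheme(
            mode="user", thresholds=tuple(int(t) for t in user_thresholds),
            cutoff=int(user_thresholds[0]),
        )
    if hash_seeds is None:
        hash_seeds = HASH_SEEDS[:h]

    # Pass 1: count minimizers and fix thresholds per experiment.
    all_counts: list[ExperimentCounts] = []
    schemes: list[ThresholdScheme] = []
    for name, files in experiments:
        counts = count_minimizers(files, params)
        all_counts.append(counts)
        if mode == "user":
            schemes.append(global_scheme)
        else:
            t1 = cutoff_for_file_size(_file_sizes(files)) if cutoff == "auto" else int(cutoff)
            schemes.append(auto_thresholds(counts, q, t1))

    # Assign each distinct minimizer its level; tally actual loads.
    b = len(experiments)
    per_level_values: list[list[np.ndarray]] = [[] for _ in range(q)]
    actual_loads = np.zeros((b, q), dtype=np.int64)
    for e, (counts, scheme) in enumerate(zip(all_counts, schemes)):
        buckets: list[list[int]] = [[] for _ in range(q)]
        for value, count in counts.counts.items():
            lvl = level_of(count, scheme)
            if lvl >= 1:
                buckets[lvl - 1].append(value)
        for i in range(q):
            arr = np.array(buckets[i], dtype=np.uint64)
            per_level_values[i].append(arr)
            actual_loads[e, i] = arr.size

    # Size the levels: halving prediction in auto mode, exact histograms in
    # user mode.
    if mode == "auto":
        predicted = np.array(
            [predicted_auto_loads(c.total_minimizers, q) for c in all_counts]
        )
    else:
        predicted = actual_loads.astype(float)
    sizes = plan_level_sizes(predicted, h, target_fpr)

    ibfs = []
    level_fprs = np.zeros((b, q), dtype=float)
    for i in range(q):
        ibf = InterleavedBloomFilter(b, BloomSpec(n=sizes[i], h=h, hash_seeds=tuple(hash_seeds)))
        for e in range(b):
            ibf.insert_many(per_level_values[i][e], e)
            level_fprs[e, i] = false_positive_rate(sizes[i], int(actual_loads[e, i]), h)
        ibfs.append(ibf)

    divisors = [s.t2 for s in schemes] if (mode == "auto" and q >= 2) else None
    return QQIndex(
        params=params, q=q, h=h, target_fpr=target_fpr, ibfs=ibfs,
        experiments=list(names), schemes=schemes, level_fprs=level_fprs,
        normalization_divisors=divisors,
    )


def save_index(index: QQIndex, path: str | Path) -> None:
    """Write the index as a directory: ``meta.json`` + ``level_<i>.bin``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "magic": "qqfilter-index",
        "version": INDEX_VERSION,
        "k": index.params.k,
        "w": index.params.w,
        "order_seed": index.params.order_seed,
        "q": index.q,
        "h": index.h,
        "hash_seeds": list(index.ibfs[0].spec.hash_seeds),
        "target_fpr": index.target_fpr,
        "experiments": index.experiments,
        "mode": index.mode,
        "thresholds": [list(s.thresholds) for s in index.schemes],
        "cutoffs": [s.cutoff for s in index.schemes],
        "level_fprs": index.level_fprs.tolist(),
        "level_sizes": [ibf.spec.n for ibf in index.ibfs],
        "normalization_divisors": index.normalization_divisors,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for i, ibf in enumerate(index.ibfs, start=1):
        (path / f"level_{i}.bin").write_bytes(ibf.to_bytes())


def load_index(path: str | Path) -> QQIndex:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"{path} is not an index directory (meta.json missing)")
    meta = json.loads(meta_path.read_text())
    if meta.get("magic") != "qqfilter-index" or meta.get("version") != INDEX_VERSION:
        raise ValueError(
            f"unsupported index at {path}: expected magic 'qqfilter-index' "
            f"version {INDEX_VERSION}, got {meta.get('magic')!r} "
            f"version {meta.get('version')!r}"
        )
    params = MinimizerParams(k=meta["k"], w=meta["w"], order_seed=meta["order_seed"])
    ibfs = []
    for i in range(1, meta["q"] + 1):
        blob = (path / f"level_{i}.bin").read_bytes()
        ibf = InterleavedBloomFilter.from_bytes(blob)
        if ibf.spec.n != meta["level_sizes"][i - 1] or ibf.b != len(meta["experiments"]):
            raise ValueError(f"level_{i}.bin inconsistent with meta.json")
        ibfs.append(ibf)
    schemes = [
        ThresholdScheme(mode=meta["mode"], thresholds=tuple(t), cutoff=c)
        for t, c in zip(meta["thresholds"], meta["cutoffs"])
    ]
    return QQIndex(
        params=params, q=meta["q"], h=meta["h"], target_fpr=meta["target_fpr"],
        ibfs=ibfs, experiments=list(meta["experiments"]), schemes=schemes,
        level_fprs=np.array(meta["level_fprs"], dtype=float),
        normalization_divisors=meta["normalization_divisors"],
    )
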