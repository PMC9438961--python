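"""Count cutoffs and level thresholds for the q-quantitative filter.

Level ``i`` of the filter holds minimizers whose occurrence count ``c``
satisfies ``t_i <= c < t_{i+1}``; the last level holds every count
``>= t_q``.  Counts below the cutoff ``t_1`` are discarded as probable
sequencing noise.  Thresholds are either user-supplied (one global ascending
list) or derived automatically per experiment by recursively taking the
median of the counts still at or above the previous threshold -- which halves
the minimizer content at every level.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np

from .sketch import ExperimentCounts

logger = logging.getLogger(__name__)

_MB = 10**6

# (upper bound of gzipped input size in bytes, cutoff); open-ended last bracket
_CUTOFF_BRACKETS = (
    (300 * _MB, 1),
    (500 * _MB, 3),
    (1000 * _MB, 10),
    (3000 * _MB, 20),
)


@dataclass(frozen=True)
class ThresholdScheme:
    """Level boundaries ``t_1..t_q`` for one experiment (or globally).

    ``mode`` is "user" (one global list) or "auto" (per-experiment recursive
    medians); ``cutoff`` records the provenance of ``t_1``.
    """

    mode: str
    thresholds: tuple[int, ...]
    cutoff: int

    def __post_init__(self) -> None:
        if self.mode not in ("user", "auto"):
            raise ValueError(f"mode must be 'user' or 'auto', got {self.mode!r}")
        if len(self.thresholds) < 1:
            raise ValueError("need at least one threshold")
        if any(b < a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"thresholds must be ascending: {self.thresholds}")

    @property
    def q(self) -> int:
        return len(self.thresholds)

    @property
    def t2(self) -> int:
        """Normalization divisor (second-level threshold)."""
        if self.q < 2:
            raise ValueError("no second level: q < 2")
        return self.thresholds[1]


def cutoff_for_file_size(size_bytes: int) -> int:
    """File-size-dependent count cutoff for gzipped inputs.

    1 for <= 300 MB, 3 for (300, 500], 10 for (500, 1000], 20 for
    (1000, 3000] and 50 above (MB = 10^6 bytes).
    """
    if size_bytes < 0:
        raise ValueError("size_bytes must be >= 0")
    for upper, cutoff in _CUTOFF_BRACKETS:
        if size_bytes <= upper:
            return cutoff
    return 50


def _lower_median(sorted_arr: np.ndarray) -> int:
    return int(sorted_arr[(sorted_arr.size - 1) // 2])


def auto_thresholds(counts: ExperimentCounts, q: int, t1: int) -> ThresholdScheme:
    """Per-experiment thresholds by recursive lower medians.

    ``t_1 = t1``; for ``i >= 2``, ``t_i`` is the lower median of the counts
    of minimizers whose count is ``>= t_{i-1}``.  Each recursion step halves
    the surviving minimizer content.  An exhausted tail repeats the previous
    threshold; empty input yields all thresholds equal to the cutoff.
    """
    if q < 2:
        raise ValueError("automatic thresholds need q >= 2")
    if t1 < 1:
        raise ValueError("cutoff t1 must be >= 1")
    arr = np.sort(np.fromiter(counts.counts.values(), dtype=np.int64))
    arr = arr[arr >= t1]
    if arr.size == 0:
        logger.warning("no minimizer count reaches the cutoff %d", t1)
        return ThresholdScheme(mode="auto", thresholds=(t1,) * q, cutoff=t1)
    thresholds = [t1]
    for _ in range(q - 1):
        arr = arr[arr >= thresholds[-1]]
        thresholds.append(_lower_median(arr) if arr.size else thresholds[-1])
    return ThresholdScheme(mode="auto", thresholds=tuple(thresholds), cutoff=t1)


def level_of(count: int, scheme: ThresholdScheme) -> int:
    """Level index for an occurrence count: 0 (discarded) if below ``t_1``,
    ``i`` if ``t_i <= count < t_{i+1}``, ``q`` if ``count >= t_q``."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return bisect.bisect_right(scheme.thresholds, count)
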