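"""Expression estimation: query the q-quantitative filter with transcripts.

The expression value of a transcript in an experiment is defined as the
median of its minimizer occurrence counts.  The index stores only which
*level* each minimizer's count fell into, so the median is approximated:

1. count the transcript's ``m`` minimizers at every level (one bulk IBF pass
   per level, so a query costs exactly ``q`` passes);
2. correct each observed count ``n_o`` for that level's per-experiment
   false-positive rate, ``n_tp = (n_o - m*fpr) / (1 - fpr)``;
3. scanning from the top level down, find the level ``x`` at which the
   corrected count ``a`` plus everything above it ``b`` first reaches half of
   ``m`` while ``b`` alone is still below half;
4. linearly interpolate the median between the bounding thresholds
   ``T_x = t_x`` and ``T_y = t_{x+1}``:
   ``mu = T_y - (T_y - T_x) * ((m/2 - b) / a)``, clamped to ``[T_x, T_y]``.
   If the top level itself absorbs the half, ``mu = t_q``.

A transcript for which no level satisfies the half-coverage rule is reported
as not expressed (estimate 0, distinct from a true count at the cutoff).
Optionally the estimate is normalized by the experiment's second-level
threshold ``t_2``, a coverage-dependent divisor (automatic thresholds only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .build import QQIndex
from .sketch import MinimizerParams, minimizer_values, _open_maybe_gzip
from .thresholds import ThresholdScheme

logger = logging.getLogger(__name__)


@dataclass
class QuerySketch:
    """Run-compressed minimizer multiset of one query transcript."""

    transcript_id: str
    values: list[int]
    params: MinimizerParams | None = None

    @property
    def m(self) -> int:
        return len(self.values)


@dataclass
class LevelCounts:
    """Observed and false-positive-corrected per-level hit counts.

    ``raw[i][e]`` is how many of the query's ``m`` minimizers level ``i+1``
    reported present for experiment ``e``; ``corrected`` estimates the true
    positives among them.
    """

    raw: np.ndarray  # (q, b) int
    corrected: np.ndarray  # (q, b) float


@dataclass
class ExpressionEstimate:
    transcript_id: str
    estimates: np.ndarray  # (b,) approximated medians mu_e
    normalized: np.ndarray | None = None  # mu_e / t2(e)


def sketch_transcript(
    transcript_id: str, seq: str, params: MinimizerParams
) -> QuerySketch:
    return QuerySketch(transcript_id, minimizer_values(seq, params), params)


def min_hits_to_estimate(m: int) -> int:
    """Minimum number of found minimizers that can trigger an estimate:
    the smallest integer reaching half of ``m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return (m + 1) // 2


def corrected_count(raw: float, m: int, fpr: float) -> float:
    """True-positive estimate from an observed count at one level:
    ``(raw - m*fpr) / (1 - fpr)``, floored at 0 and capped at ``raw``."""
    if fpr >= 1.0:
        return 0.0
    return float(min(max(0.0, (raw - m * fpr) / (1.0 - fpr)), raw))


def query_level_counts(index: QQIndex, sketch: QuerySketch) -> LevelCounts:
    """One bulk-count IBF pass per level, then per-experiment FP correction."""
    if sketch.params is not None and sketch.params != index.params:
        raise ValueError(
            f"sketch parameter mismatch: query used {sketch.params}, "
            f"index was built with {index.params}"
        )
    q, b = index.q, index.b
    raw = np.zeros((q, b), dtype=np.int64)
    values = np.asarray(sketch.values, dtype=np.uint64)
    for i, ibf in enumerate(index.ibfs):
        raw[i] = ibf.bulk_counts(values)
        index.query_passes += 1
    corrected = np.zeros((q, b), dtype=float)
    for i in range(q):
        for e in range(b):
            corrected[i, e] = corrected_count(raw[i, e], sketch.m, index.level_fprs[e, i])
    return LevelCounts(raw=raw, corrected=corrected)


def select_levels(
    counts: LevelCounts, m: int, experiment: int
) -> tuple[int, int, float, float] | None:
    """Top-down scan for the interpolation level pair of one experiment.

    Returns ``(x, y, a, b)`` with 1-based levels ``x`` and ``y = min(x+1, q)``,
    ``a`` the corrected count at level ``x`` and ``b`` the corrected counts
    summed over all levels above; or ``None`` if the transcript is not
    expressed.  The half comparisons are performed as ``2(a+b) >= m`` and
    ``2b < m`` so odd ``m`` needs no rounding convention.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    q = counts.corrected.shape[0]
    b_run = 0.0
    for x in range(q, 0, -1):
        a = float(counts.corrected[x - 1, experiment])
        if 2.0 * (a + b_run) >= m and 2.0 * b_run < m:
            return x, min(x + 1, q), a, b_run
        b_run += a
    return None


def interpolate_median(
    selection: tuple[int, int, float, float] | None,
    m: int,
    scheme: ThresholdScheme,
) -> float:
    """Approximate median from a level selection; 0 if not expressed.

    At the top level there is no upper bound to interpolate towards, so the
    estimate is the level's own threshold ``t_q``.
    """
    if selection is None:
        return 0.0
    x, y, a, b = selection
    t = scheme.thresholds
    if x == scheme.q:
        return float(t[-1])
    assert a > 0.0, "select_levels returned a level with zero count"
    t_x, t_y = float(t[x - 1]), float(t[y - 1])
    mu = t_y - (t_y - t_x) * ((m / 2.0 - b) / a)
    return float(min(max(mu, t_x), t_y))


def normalize(mu: float, scheme: ThresholdScheme) -> float:
    """Coverage normalization: divide by the second-level threshold ``t_2``."""
    if scheme.mode != "auto":
        raise ValueError("normalization requires automatic thresholds")
    return mu / scheme.t2


def estimate_sketch(index: QQIndex, sketch: QuerySketch, *, normalized: bool = False) -> ExpressionEstimate:
    b = index.b
    mus = np.zeros(b, dtype=float)
    if sketch.m >= 1:
        counts = query_level_counts(index, sketch)
        for e in range(b):
            sel = select_levels(counts, sketch.m, e)
            mus[e] = interpolate_median(sel, sketch.m, index.schemes[e])
    norm = None
    if normalized:
        norm = np.array([normalize(mus[e], index.schemes[e]) for e in range(b)])
    return ExpressionEstimate(sketch.transcript_id, mus, norm)


def estimate_file(
    index: QQIndex,
    transcripts: str | Path,
    *,
    normalized: bool = False,
) -> pd.DataFrame:
    """Estimate every transcript of a FASTA file against every experiment.

    Returns a DataFrame with a ``transcript`` column followed by one column
    per experiment; a transcript shorter than the window yields 0 with a
    warning; the estimates are deterministic for a fixed index.
    """
    rows = []
    path = Path(transcripts)
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq)
            sketch = sketch_transcript(record.id, seq, index.params)
            if sketch.m == 0:
                logger.warning(
                    "transcript %s shorter than window w=%d: estimate 0",
                    record.id, index.params.w,
                )
            est = estimate_sketch(index, sketch, normalized=normalized)
            values = est.normalized if normalized else est.estimates
            rows.append([record.id, *values])
    return pd.DataFrame(rows, columns=["transcript", *index.experiments])
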