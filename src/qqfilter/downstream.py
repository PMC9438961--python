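"""Small downstream analyses over expression matrices.

Covers the titration consistency check for two-sample mixtures (samples C
and D mixed 3:1 and 1:3 from A and B), overexpression calling against the
per-sample mean, and the resulting confusion matrix.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def titration_ratio(a: float, b: float) -> float:
    """Expected D/C expression ratio for mixtures C = 3A+B, D = A+3B:
    ``(A + 3B) / (3A + B)``.  Always in [1/3, 3] for non-negative inputs."""
    denom = 3.0 * a + b
    if denom == 0:
        raise ZeroDivisionError("titration ratio undefined for A = B = 0")
    return (a + 3.0 * b) / denom


def titration_mse(table: pd.DataFrame) -> float:
    """Mean squared error between the observed D/C ratio and the expected
    titration ratio from A and B, per gene.

    ``table`` needs columns A, B, C, D indexed by gene.  Genes where the
    expectation or observation is undefined (A = B = 0 or C = 0) are
    excluded and logged.
    """
    for col in ("A", "B", "C", "D"):
        if col not in table.columns:
            raise ValueError(f"titration table needs column {col!r}")
    if len(table) == 0:
        raise ValueError("titration table is empty")
    errors = []
    for gene, row in table.iterrows():
        if (row.A == 0 and row.B == 0) or row.C == 0:
            logger.info("gene %s excluded from titration MSE (zero expression)", gene)
            continue
        expected = titration_ratio(row.A, row.B)
        observed = row.D / row.C
        errors.append((observed - expected) ** 2)
    if not errors:
        raise ValueError("no gene with defined titration ratio")
    return float(np.mean(errors))


def overexpression_calls(matrix: pd.DataFrame, gene: str) -> pd.Series:
    """Per-sample overexpression call for ``gene``: expression strictly
    greater than the mean expression over all genes of that sample.

    ``matrix`` is genes x samples.  The caller controls the gene universe the
    mean is taken over (e.g. all protein-coding genes).
    """
    if gene not in matrix.index:
        near = difflib.get_close_matches(gene, [str(g) for g in matrix.index], n=3)
        raise KeyError(f"gene {gene!r} not in matrix; near matches: {near}")
    return matrix.loc[gene] > matrix.mean(axis=0)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def fnr(self) -> float:
        return self.fn / (self.fn + self.tp) if (self.fn + self.tp) else 0.0


def confusion_matrix(calls, truth) -> ConfusionMatrix:
    """2x2 tallies of boolean calls against boolean truth, sample-aligned."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError(f"calls ({calls.shape}) and truth ({truth.shape}) differ in length")
    return ConfusionMatrix(
        tp=int(np.sum(calls & truth)),
        fp=int(np.sum(calls & ~truth)),
        tn=int(np.sum(~calls & ~truth)),
        fn=int(np.sum(~calls & truth)),
    )


def differential_expression_ttest(
    matrix: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Convenience wrapper: per-gene two-sample t-test between two sample
    groups with Bonferroni correction by the number of genes tested.

    This is a thin shim over :func:`scipy.stats.ttest_ind`; it exists so a
    prefilter run can be triaged quickly, not as a substitute for a proper
    differential-expression model.
    """
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1)
    p_adj = np.minimum(p * len(matrix), 1.0)
    return pd.DataFrame(
        {"t": t, "pvalue": p, "pvalue_bonferroni": p_adj}, index=matrix.index
    )
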