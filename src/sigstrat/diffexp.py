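"""Two-group differential expression: Welch's t, BH adjustment, volcano
filtering and the direction-concordant two-cohort intersection.

The log2 fold change is the difference of group means on the log2 CPM scale
(matching volcano-plot axes); a gene "passes" when |log2FC| clears the
fold-change threshold and its BH-adjusted p clears the cohort's FDR
threshold. The two-cohort intersection keeps genes passing in both cohorts
with the same direction of change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import ExpressionMatrix, Scale
from .stratification import GroupAssignment

__all__ = [
    "DeThresholds",
    "welch_t",
    "bh_adjust",
    "differential_table",
    "concordant_intersection",
    "IntersectionSummary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeThresholds:
    """Volcano pass thresholds: fold 4 (log2 scale 2) and per-cohort FDR."""

    min_abs_log2fc: float = 2.0
    max_q: float = 0.10

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.max_q <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class IntersectionSummary:
    only_a: int
    only_b: int
    shared: int
    shared_genes: list[str]


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; Welch statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    thresholds: DeThresholds = DeThresholds(),
) -> pd.DataFrame:
    """Per-gene Welch/BH differential expression table (high vs low).

    Requires a log2-scale matrix (fold change is mean difference of log2
    values). Genes with zero variance in both groups are dropped and logged.
    Columns: mean_high, mean_low, log2fc, t, df, p, q, direction, passes.
    """
    if matrix.scale is not Scale.log2CPM:
        raise ValueError(
            f"differential_table requires log2CPM scale, got {matrix.scale.value}"
        )
    high = groups.high
    low = groups.low
    if not high or not low:
        raise ValueError("both groups must be non-empty")
    a = matrix.values[high].to_numpy()
    b = matrix.values[low].to_numpy()
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        dropped = list(np.array(matrix.gene_ids)[degenerate])
        logger.info("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
    keep = ~degenerate
    genes = np.array(matrix.gene_ids)[keep]
    a, b = a[keep], b[keep]
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    mean_high = a.mean(axis=1)
    mean_low = b.mean(axis=1)
    log2fc = mean_high - mean_low
    q = bh_adjust(res.pvalue)
    table = pd.DataFrame(
        {
            "mean_high": mean_high,
            "mean_low": mean_low,
            "log2fc": log2fc,
            "t": res.statistic,
            "df": res.df,
            "p": res.pvalue,
            "q": q,
            "direction": np.sign(log2fc).astype(int),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    table["passes"] = (np.abs(table["log2fc"]) >= thresholds.min_abs_log2fc) & (
        table["q"] < thresholds.max_q
    )
    return table


def concordant_intersection(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> IntersectionSummary:
    """Euler-diagram counts: genes passing in both cohorts with equal direction.

    Tables are differential_table outputs (pass flags already encode each
    cohort's thresholds).
    """
    pass_a = set(table_a.index[table_a["passes"]])
    pass_b = set(table_b.index[table_b["passes"]])
    shared = sorted(
        g
        for g in pass_a & pass_b
        if table_a.loc[g, "direction"] == table_b.loc[g, "direction"]
    )
    return IntersectionSummary(
        only_a=len(pass_a - set(shared)),
        only_b=len(pass_b - set(shared)),
        shared=len(shared),
        shared_genes=shared,
    )
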