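"""Robust cohort stratification by average MAD-modified z-score.

Each gene is standardized across samples with the median / median absolute
deviation analogue of the z-score (consistency constant 0.6745 so values
are comparable to standard z under normality); a sample's activity is the
mean modified z over signature genes, and the cohort's extremes (top-k and
bottom-k by that activity) form the high/low contrast groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix

__all__ = [
    "MadZeroPolicy",
    "StratificationParams",
    "GroupAssignment",
    "mad_zscore",
    "signature_activity",
    "select_extremes",
]

logger = logging.getLogger(__name__)


class MadZeroPolicy(str, Enum):
    zero = "zero"
    drop_gene = "drop_gene"
    error = "error"


@dataclass(frozen=True)
class StratificationParams:
    k: int = 20
    consistency_constant: float = 0.6745
    mad_zero_policy: MadZeroPolicy = MadZeroPolicy.zero

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class GroupAssignment:
    """Per-sample high/low/unassigned labels with the ranking scores."""

    labels: pd.Series  # values in {"high", "low", "unassigned"}
    scores: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"high", "low", "unassigned"}
        if bad:
            raise ValueError(f"invalid labels: {bad}")

    def samples(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def high(self) -> list[str]:
        return self.samples("high")

    @property
    def low(self) -> list[str]:
        return self.samples("low")


def mad_zscore(
    values: Sequence[float] | pd.Series,
    params: StratificationParams = StratificationParams(),
    gene: str = "?",
) -> np.ndarray:
    """MAD-modified z-score of one gene's values across samples.

    z_i = c * (x_i - median(x)) / MAD(x), MAD = median(|x - median(x)|),
    with c the consistency constant. A zero MAD is handled per policy:
    "zero" returns all zeros, "drop_gene" returns NaNs for the caller to
    drop, "error" raises naming the gene.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        policy = params.mad_zero_policy
        if policy is MadZeroPolicy.error:
            raise ValueError(f"MAD is zero for gene {gene!r}")
        if policy is MadZeroPolicy.drop_gene:
            return np.full_like(x, np.nan)
        return np.zeros_like(x)
    return params.consistency_constant * (x - med) / mad


def signature_activity(
    matrix: ExpressionMatrix,
    signature: Sequence[str],
    params: StratificationParams = StratificationParams(),
) -> pd.Series:
    """Per-sample mean MAD-modified z over the signature genes present."""
    sig = [g.upper() for g in signature]
    present = [g for g in sig if g in set(matrix.gene_ids)]
    missing = sorted(set(sig) - set(present))
    if not present:
        raise ValueError("no signature genes found in the matrix")
    if missing:
        logger.info("signature genes absent from matrix: %s", missing)
    z_rows = []
    for g in present:
        z = mad_zscore(matrix.values.loc[g], params, gene=g)
        if not np.all(np.isnan(z)):
            z_rows.append(z)
    if not z_rows:
        raise ValueError("every signature gene was dropped (zero MAD)")
    avg = np.nanmean(np.vstack(z_rows), axis=0)
    return pd.Series(avg, index=matrix.sample_ids, name="activity")


def select_extremes(
    scores: pd.Series, params: StratificationParams = StratificationParams()
) -> GroupAssignment:
    """Assign the k highest-scoring samples to "high", k lowest to "low".

    Ranking ties are broken by sample-id order, so the assignment is
    deterministic; tied boundaries are logged.
    """
    n = len(scores)
    if 2 * params.k > n:
        raise ValueError(f"2k = {2 * params.k} exceeds cohort size {n}")
    # stable sort on score after sorting index => ties broken by sample id
    frame = (
        pd.DataFrame({"score": scores})
        .sort_index()
        .sort_values(by="score", kind="stable", ascending=False)
    )
    ordered = frame.index.to_list()
    high = ordered[: params.k]
    low = ordered[-params.k :]
    if n > 2 * params.k:
        boundary_hi = frame["score"].iloc[params.k - 1], frame["score"].iloc[params.k]
        boundary_lo = frame["score"].iloc[-params.k - 1], frame["score"].iloc[-params.k]
        if boundary_hi[0] == boundary_hi[1] or boundary_lo[0] == boundary_lo[1]:
            logger.warning("tied scores across a selection boundary; ties broken by sample id")
    labels = pd.Series("unassigned", index=scores.index, dtype=object)
    labels.loc[high] = "high"
    labels.loc[low] = "low"
    return GroupAssignment(labels=labels, scores=scores)
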