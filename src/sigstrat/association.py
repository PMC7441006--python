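"""Pearson correlation with Fisher-z confidence intervals.

The confidence interval transforms r to z = atanh(r), which is approximately
normal with standard deviation 1/sqrt(n - 3); the interval is
tanh(z -/+ z*(level)/sqrt(n - 3)). The p-value refers
t = r * sqrt((n - 2) / (1 - r^2)) to the t distribution with n - 2 degrees
of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Sidedness",
    "CorrelationEstimate",
    "pearson_r",
    "fisher_ci",
    "correlation_p",
    "correlate",
    "correlate_columns",
]

logger = logging.getLogger(__name__)


class Sidedness(str, Enum):
    one = "one"
    two = "two"


@dataclass
class CorrelationEstimate:
    r: float
    n: int
    ci_low: float
    ci_high: float
    level: float
    p: float
    sidedness: Sidedness

    def __post_init__(self) -> None:
        if not (-1 <= self.ci_low <= self.r <= self.ci_high <= 1):
            raise ValueError("confidence bounds must bracket r within [-1, 1]")
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient; constant vectors are an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    z = atanh(r); half-width = z*(level) / sqrt(n - 3); bounds are
    tanh(z -/+ half-width). |r| = 1 yields the degenerate interval (r, r)
    with a warning.
    """
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        warnings.warn("|r| = 1: degenerate confidence interval")
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlation_p(r: float, n: int, sidedness: Sidedness | str = Sidedness.two) -> float:
    """p-value for H0: rho = 0 via the t transform with n - 2 df."""
    sidedness = Sidedness(sidedness)
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p_two = 2 * stats.t.sf(abs(t), df=n - 2)
    return float(p_two / 2 if sidedness is Sidedness.one else p_two)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    sidedness: Sidedness | str = Sidedness.two,
) -> CorrelationEstimate:
    """Full correlation estimate for one pair of aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = pearson_r(x, y)
    n = int(x.size)
    if abs(r) == 1:
        lo, hi = fisher_ci(r, n, level)
        return CorrelationEstimate(
            r=r, n=n, ci_low=lo, ci_high=hi, level=level, p=0.0,
            sidedness=Sidedness(sidedness),
        )
    lo, hi = fisher_ci(r, n, level)
    p = correlation_p(r, n, sidedness)
    return CorrelationEstimate(
        r=r, n=n, ci_low=lo, ci_high=hi, level=level, p=p, sidedness=Sidedness(sidedness)
    )


def correlate_columns(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    level: float = 0.95,
    sidedness: Sidedness | str = Sidedness.two,
) -> dict[tuple[str, str], CorrelationEstimate | Exception]:
    """Correlate requested column pairs using pairwise-complete observations.

    Samples missing in either column of a pair are dropped for that pair
    only. A pair with fewer than three complete observations yields an
    exception object in the result map; other pairs are unaffected.
    """
    out: dict[tuple[str, str], CorrelationEstimate | Exception] = {}
    for cx, cy in pairs:
        sub = table[[cx, cy]].dropna()
        if len(sub) < len(table):
            logger.info("pair (%s, %s): dropped %d incomplete rows", cx, cy, len(table) - len(sub))
        try:
            if len(sub) < 3:
                raise ValueError(f"pair ({cx}, {cy}): fewer than 3 complete observations")
            out[(cx, cy)] = correlate(sub[cx], sub[cy], level=level, sidedness=sidedness)
        except ValueError as exc:
            out[(cx, cy)] = exc
    return out
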