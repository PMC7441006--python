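"""Single-sample GSEA projection and two-class permutation GSEA.

Two statistics live here. The single-sample projection replaces each
sample's expression values by ranks and walks the genome in rank order,
accumulating the difference between the alpha-weighted in-set cumulative
rank mass and the uniform out-of-set cumulative count; the score is the sum
of that running difference over all positions. The two-class statistic ranks
genes by a variance-floored signal-to-noise ratio between phenotype groups,
computes the classic weighted Kolmogorov–Smirnov enrichment score (weight
exponent 1), and calibrates it against phenotype-label permutations:
NES = ES / mean(|null ES|) over the sign-matched null, the p-value is the
same-sign null tail fraction, and q is the GSEA false-discovery ratio of
normalized null to observed tail fractions.

Ties in expression are broken by gene-id lexicographic order so the scores
are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix, SignatureCollection

__all__ = [
    "CombineMode",
    "SsgseaParams",
    "ScoreTable",
    "EnrichmentResult",
    "ssgsea_score",
    "score_signatures",
    "combine_updn",
    "gsea_two_class",
    "filter_geneset_categories",
    "concordant_enrichment",
]


class CombineMode(str, Enum):
    add = "add"
    off = "off"
    replace = "replace"


class SampleNorm(str, Enum):
    none = "none"
    rank = "rank"


@dataclass(frozen=True)
class SsgseaParams:
    """Single-sample projection parameters.

    alpha is the rank-weighting exponent; combine_mode governs how paired
    X_UP / X_DN signatures are merged into a single activity score;
    sample_norm "none" reports the raw running-sum score without any
    post-hoc min–max rescaling.
    """

    alpha: float = 0.75
    combine_mode: CombineMode = CombineMode.add
    sample_norm: SampleNorm = SampleNorm.none

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class ScoreTable:
    """Signatures x samples grid of per-sample enrichment scores."""

    values: pd.DataFrame  # index: signature names, columns: sample ids

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("scores must be finite")

    @property
    def signatures(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EnrichmentResult:
    """Two-class GSEA result for one gene set."""

    signature: str
    es: float
    nes: float
    p: float
    q: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.es))


def _sample_rank_order(values: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Rank one sample's genes descending by expression.

    Returns (order, ranks): ``order`` indexes genes from the highest-expressed
    to lowest, ties broken by gene-id lexicographic order; ``ranks`` assigns
    the largest rank value N to the highest-expressed gene, following the same
    walk.
    """
    n = len(values)
    tie_break = np.argsort(values.index.to_numpy())  # lexicographic gene order
    # sort by (-expression, gene id): stable sort on expression after id sort
    expr = values.to_numpy()[tie_break]
    order = tie_break[np.argsort(-expr, kind="stable")]
    ranks = np.empty(n, dtype=np.float64)
    ranks[order] = np.arange(n, 0, -1, dtype=np.float64)
    return order, ranks


def ssgsea_score(
    matrix: ExpressionMatrix,
    signature: Sequence[str],
    params: SsgseaParams = SsgseaParams(),
) -> pd.Series:
    """Per-sample single-sample enrichment score for one gene set.

    For each sample, genes are ranked descending by expression (rank value N
    for the top gene) and the score is

        ES = sum_i [ P_in^w(i) - P_out(i) ]

    where P_in^w(i) is the cumulative sum of rank^alpha over in-set genes up
    to position i, normalized by the in-set total, and P_out(i) is the
    cumulative count of out-of-set genes normalized by N - |set|.
    """
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    present = [g.upper() for g in signature if g.upper() in gene_index]
    if not present:
        raise ValueError(f"signature has no genes in the matrix: {list(signature)[:5]}...")
    n = matrix.n_genes
    if len(present) == n:
        raise ValueError("signature covers every matrix gene; no complement to walk")
    in_set = np.zeros(n, dtype=bool)
    in_set[[gene_index[g] for g in present]] = True

    scores = {}
    for sample in matrix.sample_ids:
        order, ranks = _sample_rank_order(matrix.values[sample])
        walk_in = in_set[order]
        walk_ranks = ranks[order]
        weights = np.where(walk_in, walk_ranks**params.alpha, 0.0)
        p_in = np.cumsum(weights) / weights.sum()
        p_out = np.cumsum(~walk_in) / (n - len(present))
        scores[sample] = float(np.sum(p_in - p_out))
    return pd.Series(scores, name="score")


def score_signatures(
    matrix: ExpressionMatrix,
    signatures: SignatureCollection,
    params: SsgseaParams = SsgseaParams(),
) -> ScoreTable:
    """Score every signature in a collection and apply the UP/DN combine mode."""
    rows = {
        name: ssgsea_score(matrix, genes, params) for name, genes in signatures.items()
    }
    table = ScoreTable(values=pd.DataFrame(rows).T)
    return combine_updn(table, params.combine_mode)


def combine_updn(scores: ScoreTable, mode: CombineMode | str) -> ScoreTable:
    """Merge paired X_UP / X_DN signature scores into a net activity score.

    mode "add" appends X = score(X_UP) - score(X_DN) for each detected pair,
    keeping the originals; "replace" drops the pair after combining; "off"
    returns the input unchanged.
    """
    mode = CombineMode(mode)
    if mode is CombineMode.off:
        return scores
    values = scores.values.copy()
    names = set(values.index)
    pairs = []
    for name in scores.signatures:
        if name.endswith("_UP"):
            base = name[:-3]
            if f"{base}_DN" in names and base not in names:
                pairs.append(base)
    for base in pairs:
        values.loc[base] = values.loc[f"{base}_UP"] - values.loc[f"{base}_DN"]
    if mode is CombineMode.replace:
        drop = [f"{b}{suf}" for b in pairs for suf in ("_UP", "_DN")]
        values = values.drop(index=drop)
    return ScoreTable(values=values)


# ---------------------------------------------------------------------------
# Two-class permutation GSEA
# ---------------------------------------------------------------------------


def _signal_to_noise(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Variance-floored signal-to-noise ratio between two sample groups.

    values: genes x samples; mask_a marks group A columns. Standard GSEA
    floors each group's standard deviation at 0.2 x |group mean| (0.2 when
    the mean is zero) to prevent zero-variance blowups.
    """
    a = values[:, mask_a]
    b = values[:, ~mask_a]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = a.std(axis=1, ddof=1)
    sd_b = b.std(axis=1, ddof=1)
    floor_a = np.where(mean_a != 0, 0.2 * np.abs(mean_a), 0.2)
    floor_b = np.where(mean_b != 0, 0.2 * np.abs(mean_b), 0.2)
    sd_a = np.maximum(sd_a, floor_a)
    sd_b = np.maximum(sd_b, floor_b)
    return (mean_a - mean_b) / (sd_a + sd_b)


def _weighted_ks_es(metric: np.ndarray, in_set: np.ndarray, weight_exponent: float = 1.0) -> float:
    """Enrichment score: signed extremum of the weighted KS running sum."""
    order = np.argsort(-metric, kind="stable")
    walk_in = in_set[order]
    w = np.abs(metric[order]) ** weight_exponent
    hit = np.where(walk_in, w, 0.0)
    hit_total = hit.sum()
    if hit_total == 0:  # all in-set metrics are exactly zero
        hit = walk_in.astype(float)
        hit_total = hit.sum()
    p_hit = np.cumsum(hit) / hit_total
    p_miss = np.cumsum(~walk_in) / (len(metric) - int(walk_in.sum()))
    running = p_hit - p_miss
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _group_assignments(n: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """Yield boolean group-A masks: exhaustive when feasible, else sampled."""
    total = comb(n, n_a)
    if total <= n_perm:
        masks = []
        for idx in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            masks.append(mask)
        return masks, True
    masks = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_a]] = True
        masks.append(mask)
    return masks, False


def gsea_two_class(
    matrix: ExpressionMatrix,
    labels: Sequence[str] | pd.Series,
    signatures: SignatureCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Two-class GSEA with phenotype-label permutations.

    labels assigns each sample to one of exactly two groups; the ranking
    metric is signal-to-noise of the first group (by sorted label name)
    minus the second. When the number of distinct label assignments is at
    most n_perm the null is enumerated exhaustively; otherwise n_perm
    random permutations are drawn from the seeded generator. Signatures
    with no genes in the matrix are skipped with a warning.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation GSEA")
    labels = pd.Series(labels, index=matrix.sample_ids if not isinstance(labels, pd.Series) else None)
    if isinstance(labels.index, pd.RangeIndex):
        labels.index = matrix.sample_ids
    labels = labels.reindex(matrix.sample_ids)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    keep = labels.notna().to_numpy()
    values = matrix.values.to_numpy()[:, keep]
    lab = labels.dropna().to_numpy()
    mask_a = lab == groups[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    gene_ids = np.array(matrix.gene_ids)
    observed_metric = _signal_to_noise(values, mask_a)
    if np.allclose(observed_metric, 0):
        raise ValueError("ranking metric is identically zero; groups are indistinguishable")

    rng = np.random.default_rng(seed)
    null_masks, exhaustive = _group_assignments(len(lab), int(mask_a.sum()), n_perm, rng)
    null_metrics = [_signal_to_noise(values, m) for m in null_masks]

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    results: list[EnrichmentResult] = []
    per_set_null_nes: list[np.ndarray] = []
    observed_nes: list[float] = []
    kept_sets: list[tuple[str, float, float]] = []  # name, es, p

    for name, genes in signatures.items():
        idx = [gene_index[g] for g in (g.upper() for g in genes) if g in gene_index]
        if not idx:
            warnings.warn(f"signature {name!r} has no genes in the matrix; skipped")
            continue
        in_set = np.zeros(len(gene_ids), dtype=bool)
        in_set[idx] = True
        es = _weighted_ks_es(observed_metric, in_set, weight_exponent)
        null_es = np.array(
            [_weighted_ks_es(m, in_set, weight_exponent) for m in null_metrics]
        )
        same_sign = null_es * np.sign(es) > 0
        if same_sign.any():
            # tolerance so a null assignment identical to the observed one
            # (exhaustive mode) counts as a tie despite summation-order noise
            tol = 1e-12 * max(1.0, abs(es))
            p = float(np.sum(np.abs(null_es[same_sign]) >= abs(es) - tol) / same_sign.sum())
            nes = float(es / np.abs(null_es[same_sign]).mean())
        else:
            # no same-sign null ES at all: p is the tail bound, and the
            # overall null magnitude stands in as the normalizer
            p = 0.0
            nes = float(es / np.abs(null_es).mean()) if np.abs(null_es).mean() > 0 else 0.0
        # normalized null for the FDR step: each null ES scaled by the
        # sign-matched null mean of its own set
        pos_mean = np.abs(null_es[null_es > 0]).mean() if (null_es > 0).any() else np.nan
        neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
        null_nes = np.where(null_es >= 0, null_es / pos_mean, null_es / neg_mean)
        null_nes = null_nes[np.isfinite(null_nes)]
        per_set_null_nes.append(null_nes)
        observed_nes.append(float(nes))
        kept_sets.append((name, float(es), p))

    # GSEA FDR: for each observed NES*, q = (null tail fraction) / (observed
    # tail fraction), same sign, capped at 1.
    all_null = np.concatenate(per_set_null_nes) if per_set_null_nes else np.array([])
    obs = np.array(observed_nes)
    for (name, es, p), nes in zip(kept_sets, obs):
        if nes >= 0:
            null_pool = all_null[all_null >= 0]
            null_tail = np.mean(null_pool >= nes) if len(null_pool) else 0.0
            obs_pool = obs[obs >= 0]
            obs_tail = np.mean(obs_pool >= nes) if len(obs_pool) else 1.0
        else:
            null_pool = all_null[all_null < 0]
            null_tail = np.mean(null_pool <= nes) if len(null_pool) else 0.0
            obs_pool = obs[obs < 0]
            obs_tail = np.mean(obs_pool <= nes) if len(obs_pool) else 1.0
        q = min(1.0, float(null_tail / obs_tail)) if obs_tail > 0 else 0.0
        results.append(EnrichmentResult(signature=name, es=es, nes=float(nes), p=p, q=q))
    return results


def filter_geneset_categories(
    results: list[EnrichmentResult], category_whitelist: Sequence[str]
) -> list[EnrichmentResult]:
    """Restrict results to whitelisted gene-set names (exact or substring match).

    An empty whitelist returns the input unchanged with a warning.
    """
    if not category_whitelist:
        warnings.warn("empty gene-set whitelist; returning all results")
        return list(results)
    whitelist = list(category_whitelist)
    kept = []
    for res in results:
        if any(pat == res.signature or pat in res.signature for pat in whitelist):
            kept.append(res)
    return kept


def concordant_enrichment(
    results_a: list[EnrichmentResult],
    results_b: list[EnrichmentResult],
    max_q: float = 0.25,
) -> list[str]:
    """Gene sets significant with the same NES sign in both cohorts.

    Returns signature names, ordered as in cohort A.
    """
    by_name_b = {r.signature: r for r in results_b}
    shared = []
    for ra in results_a:
        rb = by_name_b.get(ra.signature)
        if rb is None:
            continue
        if ra.q <= max_q and rb.q <= max_q and np.sign(ra.nes) == np.sign(rb.nes) != 0:
            shared.append(ra.signature)
    return shared
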