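"""Synthetic cohorts and ChIP coverage with planted ground truth.

The expression generator is a latent-factor linear-Gaussian model: each
sample carries a latent activity a_s, each gene a loading beta_g that is
positive for signature genes, negative for repressed genes and zero
otherwise, and log2 expression is

    baseline_g + beta_g * a_s + patient effect (paired designs) + noise.

This is the simplest generative structure consistent with the analysis'
assumptions (signature genes co-vary with the activity factor; repressed
targets anti-covary). The paired variant emulates a small
microdissection-style cohort in which high- and low-activity tumor foci are
selected within patients, so the planted activity is bimodal by design; the
unpaired variant emulates a large unselected cohort with Gaussian activity.

The ChIP generator plants peaks whose heights all scale by gamma under
knockdown while a designated target peak additionally scales by phi, with
Poisson depth noise and spike-in read counts per condition — the structure
in which proportional target occupancy rises (phi > 1) even as global
binding falls (gamma < 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    CoverageTrack,
    ExpressionMatrix,
    Interval,
    IntervalSet,
    Scale,
    SignatureCollection,
)
from .chip_occupancy import SpikeInPair

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "ChipSimConfig",
    "ChipSimResult",
    "simulate_cohort",
    "simulate_chip",
    "TCGA_LIKE",
    "LCM_LIKE",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated expression cohort."""

    n_samples: int
    n_genes: int = 2000
    n_signature_genes: int = 54
    n_repressed_genes: int = 20
    activity_sd: float = 1.0
    signature_loading: tuple[float, float] = (0.7, 1.3)
    repressed_loading: tuple[float, float] = (-1.3, -0.7)
    noise_sd: float = 0.7
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    paired: bool = False
    # paired designs: foci are selected as activity-high/-low within patient,
    # so activity is bimodal with this separation (log2-activity units)
    selection_separation: float = 3.0
    within_group_sd: float = 0.5
    patient_sd: float = 0.5
    n_high: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_genes + self.n_repressed_genes > self.n_genes:
            raise ValueError("signature + repressed genes exceed total genes")
        if min(self.n_samples, self.n_genes, self.n_signature_genes) < 1:
            raise ValueError("counts must be positive")
        if self.signature_loading[0] <= 0:
            raise ValueError("signature loadings must be positive")
        if self.repressed_loading[1] >= 0:
            raise ValueError("repressed loadings must be negative")


# Named study conditions: a large unpaired cohort and a small paired cohort
# of within-patient high/low foci (8 high, 11 low).
TCGA_LIKE = CohortConfig(n_samples=499, paired=False)
LCM_LIKE = CohortConfig(n_samples=19, paired=True, n_high=8)


@dataclass
class CohortTruth:
    """Planted parameters attached to a simulated cohort."""

    activity: pd.Series  # latent a_s per sample
    loadings: pd.Series  # beta_g per gene
    signature_genes: list[str]
    repressed_genes: list[str]
    intended_labels: pd.Series  # {"high","low"} (paired) or by activity sign

    @property
    def signature(self) -> SignatureCollection:
        return SignatureCollection(
            entries={
                "ACTIVITY_SIG": list(self.signature_genes),
                "REPRESSED_SET": list(self.repressed_genes),
            }
        )


def simulate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw one cohort from the latent-factor model; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    sig_genes = gene_ids[: config.n_signature_genes]
    rep_genes = gene_ids[config.n_signature_genes : config.n_signature_genes + config.n_repressed_genes]

    beta = np.zeros(g)
    beta[: config.n_signature_genes] = rng.uniform(
        config.signature_loading[0], config.signature_loading[1], config.n_signature_genes
    )
    beta[config.n_signature_genes : config.n_signature_genes + config.n_repressed_genes] = rng.uniform(
        config.repressed_loading[0], config.repressed_loading[1], config.n_repressed_genes
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, g)

    if config.paired:
        n_high = config.n_high if config.n_high is not None else n // 2
        labels = np.array(["high"] * n_high + ["low"] * (n - n_high))
        centers = np.where(labels == "high", config.selection_separation / 2,
                           -config.selection_separation / 2)
        activity = centers + rng.normal(0, config.within_group_sd, n)
        # within-patient foci share a patient-level baseline shift
        n_patients = (n + 1) // 2
        patient_of = np.arange(n) % n_patients
        patient_effect = rng.normal(0, config.patient_sd, n_patients)[patient_of]
    else:
        activity = rng.normal(0, config.activity_sd, n)
        labels = np.where(activity > np.median(activity), "high", "low")
        patient_effect = np.zeros(n)

    noise = rng.normal(0, config.noise_sd, (g, n))
    values = baseline[:, None] + np.outer(beta, activity) + patient_effect[None, :] + noise

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        scale=Scale.log2CPM,
    )
    truth = CohortTruth(
        activity=pd.Series(activity, index=sample_ids, name="activity"),
        loadings=pd.Series(beta, index=gene_ids, name="loading"),
        signature_genes=sig_genes,
        repressed_genes=rep_genes,
        intended_labels=pd.Series(labels, index=sample_ids, name="label"),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# ChIP coverage simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipSimConfig:
    """Study conditions for simulated per-condition ChIP coverage."""

    n_peaks: int = 60
    n_case_conditions: int = 3
    peak_width_mean: int = 400
    peak_height_lognorm_mean: float = 3.5  # log-scale mean of peak heights
    peak_height_lognorm_sd: float = 0.5
    gamma: float = 0.7  # global knockdown scale
    phi: float = 1.3  # target redistribution factor
    depth: float = 50.0  # multiplier on expected per-base counts
    spike_in_reads: int = 100_000
    primary_reads: int = 1_000_000
    bin_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("need at least one peak")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")


@dataclass
class ChipSimResult:
    tracks: dict[str, CoverageTrack]  # "control", "kd1", ...
    spikeins: dict[str, SpikeInPair]
    consensus_peaks: IntervalSet
    target: Interval
    truth: dict[str, float]  # {"gamma": ..., "phi": ...}


def _binned_track(
    peaks: list[Interval],
    heights: np.ndarray,
    depth: float,
    bin_size: int,
    rng: np.random.Generator,
) -> CoverageTrack:
    """Poisson-noised coverage: each peak emitted as fixed-width bins whose
    expected depth is the peak height (flat profile) times the depth factor."""
    records: list[tuple[str, int, int, float]] = []
    for peak, height in zip(peaks, heights):
        for start in range(peak.start, peak.end, bin_size):
            end = min(start + bin_size, peak.end)
            lam = height * depth * (end - start)
            counts = rng.poisson(lam)
            records.append((peak.chrom, start, end, counts / (depth * (end - start))))
    return CoverageTrack.from_records(records)


def simulate_chip(config: ChipSimConfig) -> ChipSimResult:
    """Simulate control + knockdown coverage over a consensus peak set.

    Knockdown conditions scale every peak height by gamma and the designated
    target peak additionally by phi; spike-in read counts are emitted per
    condition so both proportional and spike-in normalization are exercised.
    """
    rng = np.random.default_rng(config.seed)
    peaks: list[Interval] = []
    pos = 10_000
    for i in range(config.n_peaks):
        width = max(config.bin_size, int(rng.normal(config.peak_width_mean, config.peak_width_mean / 5)))
        peaks.append(Interval(chrom="chr1", start=pos, end=pos + width, name=f"peak{i:03d}"))
        pos += width + int(rng.integers(2000, 10_000))
    heights = rng.lognormal(config.peak_height_lognorm_mean, config.peak_height_lognorm_sd, config.n_peaks)

    target_idx = int(rng.integers(config.n_peaks))
    target = peaks[target_idx]

    tracks: dict[str, CoverageTrack] = {}
    spikeins: dict[str, SpikeInPair] = {}
    tracks["control"] = _binned_track(peaks, heights, config.depth, config.bin_size, rng)
    spikeins["control"] = SpikeInPair(
        condition="control",
        primary_reads=config.primary_reads,
        reference_reads=int(rng.poisson(config.spike_in_reads)),
    )
    for c in range(config.n_case_conditions):
        kd_heights = heights * config.gamma
        kd_heights[target_idx] *= config.phi
        name = f"kd{c + 1}"
        tracks[name] = _binned_track(peaks, kd_heights, config.depth, config.bin_size, rng)
        spikeins[name] = SpikeInPair(
            condition=name,
            primary_reads=int(config.primary_reads * config.gamma),
            reference_reads=int(rng.poisson(config.spike_in_reads)),
        )
    return ChipSimResult(
        tracks=tracks,
        spikeins=spikeins,
        consensus_peaks=IntervalSet(peaks),
        target=target,
        truth={"gamma": config.gamma, "phi": config.phi},
    )
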