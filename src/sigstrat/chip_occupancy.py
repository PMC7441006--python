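"""ChIP coverage occupancy statistics.

Occupancy at an interval is the area under the coverage curve (summed
depth x width over 0-based half-open overlap). Proportional occupancy
divides a target's AUC by the total over all consensus peaks — occupancy
"relative to global binding" — and is invariant to uniform depth rescaling,
so it compares conditions with different global signal. Spike-in scaling
(reads mapped to exogenous reference chromatin) provides the alternative
normalization when absolute occupancy changes matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .cohort_io import CoverageTrack, Interval, IntervalSet

__all__ = [
    "SpikeInPair",
    "AnnotationScheme",
    "Normalization",
    "OccupancyRecord",
    "interval_auc",
    "proportional_occupancy",
    "spike_in_factor",
    "occupancy_fold_change",
    "peak_overlap",
    "annotate_peaks",
    "occupancy_report",
]


@dataclass(frozen=True)
class SpikeInPair:
    """Read counts for one condition: primary genome and spike-in genome."""

    condition: str
    primary_reads: int
    reference_reads: int

    def __post_init__(self) -> None:
        if self.reference_reads <= 0:
            raise ValueError(f"{self.condition}: spike-in reference reads must be > 0")


@dataclass(frozen=True)
class AnnotationScheme:
    """Peak annotation: promoter window around TSS, then genic, then intergenic."""

    tss_window: int = 2000

    def __post_init__(self) -> None:
        if self.tss_window <= 0:
            raise ValueError("tss_window must be > 0")


class Normalization(str, Enum):
    proportional = "proportional"
    spike_in = "spike_in"


@dataclass
class OccupancyRecord:
    condition: str
    interval: Interval
    auc: float
    global_total: float
    proportional: float
    spike_factor: float = 1.0


def interval_auc(track: CoverageTrack, interval: Interval) -> float:
    """Sum of depth x overlap-width over the track runs within the interval.

    A chromosome absent from the track contributes zero coverage (warned).
    """
    if interval.chrom not in track.runs:
        warnings.warn(f"chromosome {interval.chrom!r} absent from track; AUC = 0")
        return 0.0
    starts, ends, depths = track.runs[interval.chrom]
    overlap = np.minimum(ends, interval.end) - np.maximum(starts, interval.start)
    overlap = np.clip(overlap, 0, None)
    return float(np.sum(overlap * depths))


def proportional_occupancy(
    track: CoverageTrack, consensus_peaks: IntervalSet, target: Interval
) -> float:
    """AUC at the target divided by total AUC over all consensus peaks."""
    if len(consensus_peaks) == 0:
        raise ValueError("consensus peak set is empty")
    total = sum(interval_auc(track, peak) for peak in consensus_peaks)
    if total <= 0:
        raise ValueError("zero global occupancy over consensus peaks")
    return interval_auc(track, target) / total


def spike_in_factor(sample: SpikeInPair, reference_condition: SpikeInPair) -> float:
    """Depth multiplier that equalizes expected spike-in signal to the reference.

    factor = reference_condition.reference_reads / sample.reference_reads.
    """
    return reference_condition.reference_reads / sample.reference_reads


def occupancy_fold_change(
    case_tracks: Sequence[CoverageTrack],
    control_track: CoverageTrack,
    consensus_peaks: IntervalSet,
    target: Interval,
    normalization: Normalization | str = Normalization.proportional,
    case_spikeins: Sequence[SpikeInPair] | None = None,
    control_spikein: SpikeInPair | None = None,
) -> tuple[list[float], float]:
    """Per-case and mean fold change of target occupancy versus control.

    Under proportional normalization each condition's target AUC is divided
    by its own global consensus-peak total before the case/control ratio is
    taken. Under spike-in normalization the raw AUCs are scaled by the
    spike-in factor anchored to the control condition.
    """
    normalization = Normalization(normalization)
    if not case_tracks:
        raise ValueError("need at least one case track")
    if normalization is Normalization.proportional:
        control_occ = proportional_occupancy(control_track, consensus_peaks, target)
        if control_occ == 0:
            raise ValueError("control target occupancy is zero")
        folds = [
            proportional_occupancy(track, consensus_peaks, target) / control_occ
            for track in case_tracks
        ]
    else:
        if case_spikeins is None or control_spikein is None:
            raise ValueError("spike_in normalization requires spike-in read counts")
        if len(case_spikeins) != len(case_tracks):
            raise ValueError("one SpikeInPair required per case track")
        control_auc = interval_auc(control_track, target)
        if control_auc == 0:
            raise ValueError("control target occupancy is zero")
        folds = [
            interval_auc(track, target) * spike_in_factor(pair, control_spikein) / control_auc
            for track, pair in zip(case_tracks, case_spikeins)
        ]
    return folds, float(np.mean(folds))


def _overlaps(a: Interval, b: Interval, min_bp: int) -> bool:
    return a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= min_bp


def peak_overlap(
    set_a: IntervalSet, set_b: IntervalSet, min_overlap_bp: int = 1
) -> tuple[float, float, int]:
    """Fraction of each peak set sharing >= min_overlap_bp with the other.

    Returns (shared fraction of A, shared fraction of B, count of shared
    peaks over both sets). Uses a sorted sweep per chromosome.
    """
    def shared_flags(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
        by_chrom = subject.by_chrom()
        sorted_subj = {
            c: sorted(ivs, key=lambda iv: iv.start) for c, ivs in by_chrom.items()
        }
        flags = np.zeros(len(query), dtype=bool)
        for i, q in enumerate(query):
            for s in sorted_subj.get(q.chrom, ()):
                if s.start >= q.end:
                    break
                if min(q.end, s.end) - max(q.start, s.start) >= min_overlap_bp:
                    flags[i] = True
                    break
        return flags

    if len(set_a) == 0 or len(set_b) == 0:
        return (0.0, 0.0, 0)
    flags_a = shared_flags(set_a, set_b)
    flags_b = shared_flags(set_b, set_a)
    return (
        float(flags_a.mean()),
        float(flags_b.mean()),
        int(flags_a.sum() + flags_b.sum()),
    )


def annotate_peaks(
    peaks: IntervalSet,
    tss_points: Sequence[tuple[str, int]],
    gene_intervals: IntervalSet,
    scheme: AnnotationScheme = AnnotationScheme(),
) -> dict[str, int]:
    """Assign each peak to promoter_proximal / genic_nonpromoter / intergenic.

    Precedence: a peak whose midpoint lies within scheme.tss_window of the
    nearest TSS is promoter proximal; otherwise a peak overlapping any gene
    body is genic; everything else is intergenic.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss_points:
        tss_by_chrom.setdefault(chrom, [])
    for chrom, pos in tss_points:
        tss_by_chrom[chrom].append(pos)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    genes_by_chrom = gene_intervals.by_chrom()

    counts = {"promoter_proximal": 0, "genic_nonpromoter": 0, "intergenic": 0}
    for peak in peaks:
        mid = peak.midpoint
        category = "intergenic"
        tss = tss_by_chrom.get(peak.chrom)
        if tss is not None and len(tss):
            i = np.searchsorted(tss, mid)
            nearest = min(
                (abs(mid - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss))
            )
            if nearest <= scheme.tss_window:
                category = "promoter_proximal"
        if category == "intergenic":
            for gene in genes_by_chrom.get(peak.chrom, ()):
                if min(peak.end, gene.end) - max(peak.start, gene.start) > 0:
                    category = "genic_nonpromoter"
                    break
        counts[category] += 1
    return counts


def occupancy_report(
    tracks: dict[str, CoverageTrack],
    consensus_peaks: IntervalSet,
    spikeins: dict[str, SpikeInPair] | None = None,
    control_condition: str | None = None,
) -> list[OccupancyRecord]:
    """Per-condition, per-peak occupancy records (AUC, proportional share)."""
    records: list[OccupancyRecord] = []
    for condition, track in tracks.items():
        total = sum(interval_auc(track, peak) for peak in consensus_peaks)
        if total <= 0:
            raise ValueError(f"{condition}: zero global occupancy")
        factor = 1.0
        if spikeins and control_condition:
            factor = spike_in_factor(spikeins[condition], spikeins[control_condition])
        for peak in consensus_peaks:
            auc = interval_auc(track, peak)
            records.append(
                OccupancyRecord(
                    condition=condition,
                    interval=peak,
                    auc=auc,
                    global_total=total,
                    proportional=auc / total,
                    spike_factor=factor,
                )
            )
    return records
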