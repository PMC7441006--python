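"""Materialize a fully synthetic two-cohort study on disk.

Writes everything the pipeline consumes — expression matrices, a GMT with
the planted activity signature, the planted repressed set and decoy sets,
cohort labels, ChIP coverage bedGraphs, consensus peaks — plus a truth JSON,
and returns a ready-to-run :class:`~sigstrat.pipeline.PipelineConfig`.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from .cohort_io import SignatureCollection, write_bed, write_bedgraph, write_expression_matrix, write_gmt
from .pipeline import (
    ChipSpec,
    CohortSpec,
    CorrelationPairSpec,
    GseaSpec,
    PipelineConfig,
    SpikeInSpec,
    StratifySpec,
)
from .synthetic_data import (
    LCM_LIKE,
    TCGA_LIKE,
    ChipSimConfig,
    CohortConfig,
    simulate_chip,
    simulate_cohort,
)

__all__ = ["write_synthetic_study"]


def write_synthetic_study(
    out_dir: str | Path,
    seed: int = 0,
    lcm_config: CohortConfig | None = None,
    tcga_config: CohortConfig | None = None,
    chip_config: ChipSimConfig | None = None,
    n_decoy_sets: int = 8,
    decoy_size: int = 25,
    n_perm: int = 1000,
    k: int = 20,
    include_chip: bool = True,
) -> PipelineConfig:
    """Simulate both cohorts (and optionally the ChIP arm) and write all
    pipeline inputs under ``out_dir``. Seeds for the two cohorts, the ChIP
    simulation and GSEA are derived deterministically from ``seed``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lcm_config = replace(lcm_config or LCM_LIKE, seed=seed * 7 + 1)
    tcga_config = replace(tcga_config or TCGA_LIKE, seed=seed * 7 + 2)
    lcm_matrix, lcm_truth = simulate_cohort(lcm_config)
    tcga_matrix, tcga_truth = simulate_cohort(tcga_config)

    write_expression_matrix(lcm_matrix, out_dir / "cohort_lcm.tsv")
    write_expression_matrix(tcga_matrix, out_dir / "cohort_tcga.tsv")

    labels_path = out_dir / "cohort_lcm_labels.tsv"
    with labels_path.open("w") as fh:
        fh.write("sample_id\tlabel\n")
        for sample, label in lcm_truth.intended_labels.items():
            fh.write(f"{sample}\t{label}\n")

    # signature collection: planted sets + decoys over unloaded genes
    rng = np.random.default_rng(seed * 7 + 3)
    n_planted = tcga_config.n_signature_genes + tcga_config.n_repressed_genes
    neutral = [g for g in tcga_matrix.gene_ids[n_planted:]]
    entries = {
        "ACTIVITY_SIG": list(tcga_truth.signature_genes),
        "REPRESSED_SET": list(tcga_truth.repressed_genes),
    }
    for i in range(n_decoy_sets):
        entries[f"DECOY_{i:02d}"] = list(
            rng.choice(neutral, size=min(decoy_size, len(neutral)), replace=False)
        )
    gmt_path = out_dir / "signatures.gmt"
    write_gmt(SignatureCollection(entries=entries), gmt_path)

    chip_spec = None
    chip_truth = {}
    if include_chip:
        chip_config = chip_config or ChipSimConfig(seed=seed * 7 + 4)
        sim = simulate_chip(chip_config)
        track_paths = {}
        for name, track in sim.tracks.items():
            path = out_dir / f"chip_{name}.bedgraph"
            write_bedgraph(track, path)
            track_paths[name] = str(path)
        write_bed(sim.consensus_peaks, out_dir / "consensus_peaks.bed")
        chip_spec = ChipSpec(
            tracks=track_paths,
            control="control",
            consensus_bed=str(out_dir / "consensus_peaks.bed"),
            target=(sim.target.chrom, sim.target.start, sim.target.end),
            normalization="proportional",
            spikeins={
                name: SpikeInSpec(
                    primary_reads=pair.primary_reads, reference_reads=pair.reference_reads
                )
                for name, pair in sim.spikeins.items()
            },
        )
        chip_truth = sim.truth

    repressed = tcga_truth.repressed_genes[0]
    driver = tcga_truth.signature_genes[0]
    config = PipelineConfig(
        cohort_a=CohortSpec(matrix=str(out_dir / "cohort_lcm.tsv"), labels=str(labels_path)),
        cohort_b=CohortSpec(matrix=str(out_dir / "cohort_tcga.tsv")),
        signatures_gmt=str(gmt_path),
        activity_signature="ACTIVITY_SIG",
        out_dir=str(out_dir / "results"),
        stratify=StratifySpec(k=k),
        gsea=GseaSpec(n_perm=n_perm, seed=seed * 7 + 5),
        correlations=[
            CorrelationPairSpec(cohort="b", x="score:ACTIVITY_SIG", y=f"gene:{repressed}"),
            CorrelationPairSpec(cohort="b", x=f"gene:{driver}", y=f"gene:{repressed}"),
            CorrelationPairSpec(cohort="a", x="score:ACTIVITY_SIG", y=f"gene:{repressed}"),
        ],
        chip=chip_spec,
    )
    truth = {
        "signature_genes": tcga_truth.signature_genes,
        "repressed_genes": tcga_truth.repressed_genes,
        "lcm_labels": lcm_truth.intended_labels.to_dict(),
        "chip": chip_truth,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    (out_dir / "config.json").write_text(config.model_dump_json(indent=2))
    return config
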