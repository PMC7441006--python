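"""End-to-end orchestration: score -> stratify -> differential expression ->
GSEA concordance -> correlations, plus the ChIP occupancy arm.

Stages communicate through files in the output directory so a run is
inspectable and resumable; the machine-readable report is validated against
a pydantic schema shipped with the package (``report_schema.json`` is the
exported JSON Schema). Identical config and seeds produce identical
report payloads.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .association import CorrelationEstimate, Sidedness, correlate
from .chip_occupancy import (
    Normalization,
    SpikeInPair,
    occupancy_fold_change,
)
from .cohort_io import (
    ExpressionMatrix,
    Interval,
    read_bed,
    read_bedgraph,
    read_expression_matrix,
    read_gmt,
)
from .diffexp import DeThresholds, concordant_intersection, differential_table
from .enrichment import (
    CombineMode,
    SsgseaParams,
    concordant_enrichment,
    filter_geneset_categories,
    gsea_two_class,
    score_signatures,
)
from .stratification import GroupAssignment, StratificationParams, select_extremes, signature_activity

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------


class CohortSpec(BaseModel):
    matrix: str
    scale: Literal["counts", "FPKM", "log2CPM"] = "log2CPM"
    labels: Optional[str] = None  # TSV sample_id<TAB>label; absent => stratify


class SsgseaSpec(BaseModel):
    alpha: float = 0.75
    combine_mode: Literal["add", "off", "replace"] = "add"
    sample_norm: Literal["none", "rank"] = "none"


class StratifySpec(BaseModel):
    k: int = 20
    consistency_constant: float = 0.6745
    mad_zero_policy: Literal["zero", "drop_gene", "error"] = "zero"


class DeSpec(BaseModel):
    min_abs_log2fc: float = 2.0
    max_q_cohort_a: float = 0.10
    max_q_cohort_b: float = 0.05


class GseaSpec(BaseModel):
    n_perm: int = 1000
    seed: int
    max_q: float = 0.25
    category_whitelist: list[str] = Field(default_factory=list)


class CorrelationPairSpec(BaseModel):
    cohort: Literal["a", "b"]
    x: str  # "gene:<ID>" or "score:<SIGNATURE>"
    y: str
    level: float = 0.95
    sidedness: Literal["one", "two"] = "two"


class SpikeInSpec(BaseModel):
    primary_reads: int
    reference_reads: int


class ChipSpec(BaseModel):
    tracks: dict[str, str]  # condition -> bedGraph path
    control: str
    consensus_bed: str
    target: tuple[str, int, int]
    normalization: Literal["proportional", "spike_in"] = "proportional"
    spikeins: dict[str, SpikeInSpec] = Field(default_factory=dict)


class PipelineConfig(BaseModel):
    cohort_a: CohortSpec
    cohort_b: CohortSpec
    signatures_gmt: str
    activity_signature: str
    out_dir: str
    ssgsea: SsgseaSpec = SsgseaSpec()
    stratify: StratifySpec = StratifySpec()
    diffexp: DeSpec = DeSpec()
    gsea: GseaSpec
    correlations: list[CorrelationPairSpec] = Field(default_factory=list)
    chip: Optional[ChipSpec] = None


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig.model_validate(data)


# ---------------------------------------------------------------------------
# Report schema
# ---------------------------------------------------------------------------


class CorrelationReport(BaseModel):
    cohort: str
    x: str
    y: str
    r: float
    n: int
    ci_low: float
    ci_high: float
    level: float
    p: float


class EnrichmentReport(BaseModel):
    signature: str
    es: float
    nes: float
    p: float
    q: float


class IntersectionReport(BaseModel):
    only_a: int
    only_b: int
    shared: int
    shared_genes: list[str]


class OccupancyFoldReport(BaseModel):
    normalization: str
    per_case: dict[str, float]
    mean_fold: float


class StageLog(BaseModel):
    stage: str
    seconds: float
    rows: int


class AnalysisReport(BaseModel):
    version: str
    config: PipelineConfig
    score_tables: dict[str, str]
    assignments: dict[str, str]
    de_tables: dict[str, str]
    intersection: IntersectionReport
    enrichment: dict[str, list[EnrichmentReport]]
    concordant_gene_sets: list[str]
    correlations: list[CorrelationReport]
    occupancy: Optional[OccupancyFoldReport] = None
    stage_log: list[StageLog]


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def _read_labels(path: str) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0]


def _assignment_from_labels(matrix: ExpressionMatrix, labels: pd.Series) -> GroupAssignment:
    labels = labels.reindex(matrix.sample_ids).fillna("unassigned")
    scores = pd.Series(0.0, index=matrix.sample_ids)
    return GroupAssignment(labels=labels.astype(object), scores=scores)


def _resolve_column(
    spec: str, matrix: ExpressionMatrix, scores: pd.DataFrame
) -> pd.Series:
    kind, _, name = spec.partition(":")
    if kind == "gene":
        gid = name.upper()
        if gid not in matrix.values.index:
            raise ValueError(f"gene {gid!r} not in matrix")
        return matrix.values.loc[gid]
    if kind == "score":
        if name not in scores.index:
            raise ValueError(f"signature {name!r} not in score table")
        return scores.loc[name]
    raise ValueError(f"correlation column spec must be gene:<id> or score:<name>, got {spec!r}")


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage in dependency order and write the report.

    Raises before any stage runs if a referenced input file is missing.
    Stage outputs land under config.out_dir; the report is written to
    ``report.json`` there and returned.
    """
    paths = [config.cohort_a.matrix, config.cohort_b.matrix, config.signatures_gmt]
    paths += [config.cohort_a.labels, config.cohort_b.labels]
    if config.chip:
        paths += list(config.chip.tracks.values()) + [config.chip.consensus_bed]
    missing = [p for p in paths if p and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log: list[StageLog] = []

    def log_stage(stage: str, t0: float, rows: int) -> None:
        entry = StageLog(stage=stage, seconds=round(time.perf_counter() - t0, 3), rows=rows)
        stage_log.append(entry)
        logger.info("stage %s: %d rows in %.2fs", stage, rows, entry.seconds)

    # -- load inputs
    t0 = time.perf_counter()
    matrices = {
        "a": read_expression_matrix(config.cohort_a.matrix, config.cohort_a.scale),
        "b": read_expression_matrix(config.cohort_b.matrix, config.cohort_b.scale),
    }
    signatures = read_gmt(config.signatures_gmt)
    log_stage("load", t0, sum(m.n_genes for m in matrices.values()))

    # -- ssGSEA scoring
    t0 = time.perf_counter()
    ssgsea_params = SsgseaParams(
        alpha=config.ssgsea.alpha,
        combine_mode=CombineMode(config.ssgsea.combine_mode),
    )
    score_tables = {}
    score_paths = {}
    for key, matrix in matrices.items():
        table = score_signatures(matrix, signatures, ssgsea_params)
        path = out_dir / f"scores_cohort_{key}.tsv"
        table.values.to_csv(path, sep="\t")
        score_tables[key] = table
        score_paths[key] = str(path)
    log_stage("score", t0, sum(len(t.values) for t in score_tables.values()))

    # -- stratification (or supplied labels)
    t0 = time.perf_counter()
    strat_params = StratificationParams(
        k=config.stratify.k,
        consistency_constant=config.stratify.consistency_constant,
        mad_zero_policy=config.stratify.mad_zero_policy,
    )
    activity_genes = signatures[config.activity_signature]
    assignments: dict[str, GroupAssignment] = {}
    assignment_paths = {}
    for key, matrix in matrices.items():
        spec = config.cohort_a if key == "a" else config.cohort_b
        if spec.labels:
            assignment = _assignment_from_labels(matrix, _read_labels(spec.labels))
        else:
            activity = signature_activity(matrix, activity_genes, strat_params)
            assignment = select_extremes(activity, strat_params)
        path = out_dir / f"assignment_cohort_{key}.tsv"
        pd.DataFrame({"label": assignment.labels, "score": assignment.scores}).to_csv(
            path, sep="\t", index_label="sample_id"
        )
        assignments[key] = assignment
        assignment_paths[key] = str(path)
    log_stage("stratify", t0, sum(len(a.labels) for a in assignments.values()))

    # -- differential expression + intersection
    t0 = time.perf_counter()
    de_tables = {}
    de_paths = {}
    for key, matrix in matrices.items():
        max_q = config.diffexp.max_q_cohort_a if key == "a" else config.diffexp.max_q_cohort_b
        thresholds = DeThresholds(min_abs_log2fc=config.diffexp.min_abs_log2fc, max_q=max_q)
        table = differential_table(matrix, assignments[key], thresholds)
        path = out_dir / f"diffexp_cohort_{key}.tsv"
        table.to_csv(path, sep="\t")
        de_tables[key] = table
        de_paths[key] = str(path)
    summary = concordant_intersection(de_tables["a"], de_tables["b"])
    (out_dir / "intersection.json").write_text(
        json.dumps(
            {
                "only_a": summary.only_a,
                "only_b": summary.only_b,
                "shared": summary.shared,
                "shared_genes": summary.shared_genes,
            },
            indent=2,
        )
    )
    log_stage("diffexp", t0, sum(len(t) for t in de_tables.values()))

    # -- two-class GSEA with concordance + category filter
    t0 = time.perf_counter()
    enrichment = {}
    for key, matrix in matrices.items():
        labels = assignments[key].labels
        mask = labels.isin(["high", "low"])
        sub = ExpressionMatrix(
            values=matrix.values.loc[:, mask[mask].index], scale=matrix.scale
        )
        results = gsea_two_class(
            sub,
            labels[mask],
            signatures,
            n_perm=config.gsea.n_perm,
            seed=config.gsea.seed,
        )
        enrichment[key] = results
        frame = pd.DataFrame(
            [(r.signature, r.es, r.nes, r.p, r.q) for r in results],
            columns=["signature", "es", "nes", "p", "q"],
        )
        frame.to_csv(out_dir / f"gsea_cohort_{key}.tsv", sep="\t", index=False)
    concordant = concordant_enrichment(enrichment["a"], enrichment["b"], config.gsea.max_q)
    if config.gsea.category_whitelist:
        keep = {
            r.signature
            for r in filter_geneset_categories(enrichment["a"], config.gsea.category_whitelist)
        }
        concordant = [name for name in concordant if name in keep]
    log_stage("gsea", t0, sum(len(v) for v in enrichment.values()))

    # -- correlations
    t0 = time.perf_counter()
    corr_reports: list[CorrelationReport] = []
    for pair in config.correlations:
        matrix = matrices[pair.cohort]
        scores = score_tables[pair.cohort].values
        x = _resolve_column(pair.x, matrix, scores)
        y = _resolve_column(pair.y, matrix, scores)
        est = correlate(x, y, level=pair.level, sidedness=Sidedness(pair.sidedness))
        corr_reports.append(
            CorrelationReport(
                cohort=pair.cohort, x=pair.x, y=pair.y, r=est.r, n=est.n,
                ci_low=est.ci_low, ci_high=est.ci_high, level=est.level, p=est.p,
            )
        )
    if corr_reports:
        pd.DataFrame([c.model_dump() for c in corr_reports]).to_csv(
            out_dir / "correlations.tsv", sep="\t", index=False
        )
    log_stage("correlate", t0, len(corr_reports))

    # -- ChIP occupancy arm
    occupancy = None
    if config.chip:
        t0 = time.perf_counter()
        tracks = {name: read_bedgraph(path) for name, path in config.chip.tracks.items()}
        consensus = read_bed(config.chip.consensus_bed)
        chrom, start, end = config.chip.target
        target = Interval(chrom=chrom, start=start, end=end, name="target")
        control = config.chip.control
        case_names = [n for n in tracks if n != control]
        spikeins = {
            name: SpikeInPair(name, s.primary_reads, s.reference_reads)
            for name, s in config.chip.spikeins.items()
        }
        folds, mean_fold = occupancy_fold_change(
            [tracks[n] for n in case_names],
            tracks[control],
            consensus,
            target,
            normalization=Normalization(config.chip.normalization),
            case_spikeins=[spikeins[n] for n in case_names] if spikeins else None,
            control_spikein=spikeins.get(control),
        )
        occupancy = OccupancyFoldReport(
            normalization=config.chip.normalization,
            per_case=dict(zip(case_names, folds)),
            mean_fold=mean_fold,
        )
        (out_dir / "occupancy.json").write_text(occupancy.model_dump_json(indent=2))
        log_stage("chip", t0, len(consensus))

    report = AnalysisReport(
        version=__version__,
        config=config,
        score_tables=score_paths,
        assignments=assignment_paths,
        de_tables=de_paths,
        intersection=IntersectionReport(
            only_a=summary.only_a,
            only_b=summary.only_b,
            shared=summary.shared,
            shared_genes=summary.shared_genes,
        ),
        enrichment={
            key: [
                EnrichmentReport(signature=r.signature, es=r.es, nes=r.nes, p=r.p, q=r.q)
                for r in results
            ]
            for key, results in enrichment.items()
        },
        concordant_gene_sets=concordant,
        correlations=corr_reports,
        occupancy=occupancy,
        stage_log=stage_log,
    )
    (out_dir / "report.json").write_text(report.model_dump_json(indent=2))
    return report


def export_report_schema(path: str | Path) -> None:
    """Write the JSON Schema of the analysis report (shipped artifact)."""
    Path(path).write_text(json.dumps(AnalysisReport.model_json_schema(), indent=2))
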