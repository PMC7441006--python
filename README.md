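# sigstrat

Signature scoring, robust cohort stratification, two-cohort differential
expression, permutation GSEA, Fisher-z correlation inference, and
spike-in-controlled ChIP occupancy statistics — the analysis chain used to
link a transcription factor's activity to repression of a target gene in
tumor cohorts. The motivating system is MYC-driven prostate cancer, where
high MYC activity is associated with down-regulation of the HOX-family
cofactor *MEIS1*; the package is written for computational biologists who
want each stage of that analysis as a tested, reusable function, exercised
end to end on a synthetic-data generator that plants the statistical
structure the analysis assumes.

## What it computes

**Single-sample GSEA projection.** For each sample, genes are ranked
descending by expression (rank value *N* for the top gene, ties broken by
gene id) and a gene set *S* is scored by the running sum

&nbsp;&nbsp;ES = Σᵢ [ P_inʷ(i) − P_out(i) ],&nbsp;
P_inʷ(i) = Σ_{j≤i, j∈S} r_jᵅ / Σ_{j∈S} r_jᵅ,&nbsp;
P_out(i) = #{j≤i, j∉S} / (N − |S|),

with weighting exponent α = 0.75 and combine mode `add` (paired `X_UP`/`X_DN`
sets contribute `X = UP − DN`). The score depends only on within-sample
ranks, so it is invariant to monotone transforms of one sample's values.

**MAD-modified z stratification.** Per gene,
z = 0.6745 · (x − median) / MAD with MAD = median(|x − median|); a sample's
activity is the mean z over signature genes, and the cohort's top-*k* /
bottom-*k* by that activity (default k = 20) form the activity-high /
activity-low contrast.

**Differential expression.** Welch's unequal-variance *t* per gene with
Welch–Satterthwaite degrees of freedom, Benjamini–Hochberg adjustment,
volcano filtering (|log₂FC| ≥ 2, i.e. fold 4, with per-cohort FDR
thresholds 0.10 / 0.05), and the direction-concordant intersection of two
cohorts' passing genes.

**Two-class permutation GSEA.** Genes ranked by variance-floored
signal-to-noise; weighted Kolmogorov–Smirnov enrichment score (weight
exponent 1); phenotype-label permutations (exhaustive when feasible) give
the null; NES = ES / mean(|same-sign null ES|); p is the same-sign null
tail fraction and q the GSEA ratio of normalized null to observed tail
fractions. A concordance filter retains sets significant with the same NES
sign in both cohorts.

**Correlation inference.** Pearson *r* with the Fisher-z 95% interval
tanh(atanh r ∓ z*/√(n−3)) and the t-transform p-value with n − 2 df.

**ChIP occupancy.** Interval AUC on bedGraph coverage (Σ depth × width),
proportional occupancy = target AUC / total AUC over consensus peaks
(occupancy relative to global binding, invariant to sequencing depth),
spike-in scaling anchored to the control condition, knockdown-vs-control
fold changes, peak-set overlap, and TSS-relative peak annotation.

## Worked example

The numbered scripts under `analysis/` drive the full study on synthetic
data with planted ground truth:

```bash
python analysis/01_simulate_study.py --seed 1 --out results/study
python analysis/02_run_pipeline.py   --config results/study/config.json
```

prints

```
differential expression: 0 cohort-A-only, 0 cohort-B-only, 74 shared concordant genes
concordantly enriched gene sets: ['ACTIVITY_SIG', 'REPRESSED_SET']
  cohort b: score:ACTIVITY_SIG vs gene:G00054: r=-0.7576 (95% CI -0.7926 to -0.7175, n=499, p=4.034e-94)
  cohort b: gene:G00000 vs gene:G00054: r=-0.6471 (95% CI -0.6954 to -0.5930, n=499, p=1.563e-60)
  cohort a: score:ACTIVITY_SIG vs gene:G00054: r=-0.8951 (95% CI -0.9593 to -0.7428, n=19, p=2.296e-07)
target occupancy fold (proportional, mean of 3 knockdowns): 1.2878
```

Reading this: all 74 genes passing the volcano thresholds in *both* cohorts
with the same direction are planted genes (the generator seeded 54
signature + 20 repressed genes); the planted repressed set is the gene set
found concordantly negatively enriched in activity-high vs activity-low
tumors in both cohorts; the activity score correlates negatively with a
planted repressed gene (G00054) with a confidence interval excluding zero
in both the 499-sample unpaired cohort and the 19-focus paired cohort; and
the target peak's proportional ChIP occupancy rose ≈1.29-fold under
knockdown, recovering the planted redistribution factor φ = 1.3.

Two further drivers reproduce the published correlation intervals from
their printed (r, n) pairs and the two occupancy scenarios:

```bash
python analysis/03_published_intervals.py
python analysis/04_occupancy_scenarios.py
```

The library is equally usable directly:

```python
from sigstrat.association import fisher_ci
fisher_ci(-0.4321, 19)   # (-0.7409, 0.0275)
```

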