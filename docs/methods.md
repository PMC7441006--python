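# Methods

## The analysis chain

The package implements, as composable library functions, the pipeline that
links a transcription factor's activity signature to repression of a target
gene across two expression cohorts plus a chromatin-occupancy arm:

1. **ssGSEA projection** of activity/proliferation signatures onto each
   sample (`enrichment.ssgsea_score`, `score_signatures`);
2. **robust stratification** of a cohort into activity-high and
   activity-low extremes by average MAD-modified z-score
   (`stratification`);
3. **Welch/BH differential expression** per cohort with volcano filtering
   and a direction-concordant two-cohort intersection (`diffexp`);
4. **two-class permutation GSEA** over a gene-set collection, with a
   concordance filter across cohorts and a category whitelist
   (`enrichment.gsea_two_class`, `concordant_enrichment`,
   `filter_geneset_categories`);
5. **Pearson/Fisher-z correlation inference** for score-vs-gene and
   gene-vs-gene panels (`association`);
6. **spike-in-controlled ChIP occupancy statistics** (`chip_occupancy`).

`pipeline.run_pipeline(config)` orchestrates stages 1–6 in dependency
order, communicating through files in the output directory (inspectable and
resumable rather than in-memory-only), and emits a JSON report validated by
a pydantic schema; the exported JSON Schema ships as
`sigstrat/report_schema.json`. The repository is organized as an analysis
project: the numbered scripts under `analysis/` are the command-line
surface, each a thin driver over these library functions.

## Single-sample projection

Per sample, genes are ranked descending by expression; the top gene gets
rank value N. Ties are broken by gene-id lexicographic order so scores are
deterministic. The score is the *sum* over all positions of the difference
between the rank^α-weighted in-set cumulative fraction and the uniform
out-of-set cumulative fraction (α = 0.75 by default). `sample_norm: none`
means the raw running-sum score is reported with no post-hoc min–max
rescaling. Combine mode `add` appends `X = score(X_UP) − score(X_DN)` for
each suffix-paired set, keeping the originals; `replace` drops the pair;
`off` is the identity.

A property worth knowing: with α > 0 the score of a *uniformly random*
gene set has a positive expectation (the rank-power weighting concentrates
in-set mass early in the walk), so raw scores are comparable across samples
and across sets of similar size but are not centered at zero. With α = 0
the statistic is a difference of exchangeable empirical CDFs and random
sets do center at zero; the test suite checks exactly that, and the planted
structure in all end-to-end checks is assessed through correlations and
contrasts, which are unaffected by the offset.

## Stratification

MAD-modified z uses consistency constant 0.6745 so values are comparable to
a standard z-score under normality. MAD is computed per gene across
samples — the direction forced by the use case (ranking cases). A zero MAD
is handled by policy: `zero` (default; the gene contributes nothing rather
than ±∞), `drop_gene`, or `error`. Extreme selection takes the k highest
and k lowest by average z; ranking ties are broken by sample-id order
(logged when they straddle a selection boundary), making the assignment a
pure function of the inputs.

## Differential expression

Welch's unequal-variance t with Welch–Satterthwaite degrees of freedom
(via scipy), two-sided p (the volcano shows both tails), and
Benjamini–Hochberg adjustment (via statsmodels) — "adjusted P" is read as
BH since the thresholds are stated as false discovery rates. log₂
fold-change is the difference of group means on the log₂ CPM scale,
matching volcano axes. Genes with zero variance in both groups are dropped
and logged in table mode (the bare `welch_t` errors, since the statistic is
undefined). Defaults: |log₂FC| ≥ 2 (fold 4), FDR < 0.10 for the small
paired cohort and < 0.05 for the large cohort. The small cohort's
within-patient pairing does **not** enter the test — the contrast is run
unpaired, consistent with how the volcano statistics are defined; this is a
deliberate simplification and the pairing is available in the generator for
sensitivity checks.

## Two-class GSEA

The ranking metric is signal-to-noise, (μ_A − μ_B)/(σ_A + σ_B), with each
group's σ floored at 0.2·|μ| (0.2 when μ = 0) to prevent zero-variance
blowups. ES is the signed extremum of the weighted KS running sum with
weight exponent 1. The null permutes phenotype labels: when the number of
distinct assignments C(n, n_A) is at most `n_perm` the null is enumerated
exhaustively, otherwise `n_perm` seeded random permutations are drawn.
NES = ES / mean(|null ES of matching sign|); p is the same-sign null tail
fraction, counted with an ulp-scale tolerance (1e-12 relative) so that a
null assignment identical to the observed one registers as a tie regardless
of floating-point summation order; no +1 smoothing is applied, so a planted
signal can reach p ≤ 1/n_perm. q follows the GSEA FDR convention: the
ratio of the pooled normalized-null tail fraction to the observed tail
fraction at each NES, capped at 1. Fixed seed ⇒ bit-identical results.

## Correlation inference

Fisher-z interval: tanh(atanh r ∓ z*/√(n−3)) with the normal quantile at
full precision (1.959964…). p-values use t = r√((n−2)/(1−r²)) with n − 2
df; two-sided by default with a one-sided option — back-calculating the
published panels shows the printed p-values do not follow one convention
consistently, so the interval bounds (which reproduce exactly to 4
decimals) are the quantity this package treats as authoritative. One
published panel (r = −0.5527, N = 40) prints an upper bound (−0.2713) that
no Fisher-z computation reproduces (we obtain −0.2914); it is flagged here
and excluded from the reproduction set rather than reconciled. Missing data
are dropped pairwise per requested column pair.

## ChIP occupancy

Coordinates are 0-based half-open (BED convention) throughout. Interval AUC
is Σ depth × overlap-width over bedGraph runs. Proportional occupancy —
target AUC over the summed AUC of all consensus peaks — is exactly
invariant to uniform depth rescaling, so it compares conditions with
different global signal without external calibration; spike-in scaling
(factor = control spike-in reads / condition spike-in reads, anchored to
the control) is the alternative when absolute occupancy matters. Fold
changes are per-case ratios versus control, averaged arithmetically. The
consensus-peak intersection rule and the target window (union of consensus
peaks overlapping a configured interval) are config inputs, since upstream
peak calling is out of scope. Peak annotation precedence is promoter
(midpoint within ±2000 bp of the nearest TSS) > genic > intergenic.

## Synthetic-data generator

**Expression.** A latent-factor linear-Gaussian model: log₂ expression =
baseline_g + β_g·a_s (+ patient effect in paired designs) + N(0, noise_sd).
Defaults (chosen once as the study conditions): 2,000 genes; 54 signature
genes with loadings U(0.7, 1.3); 20 repressed genes with loadings
U(−1.3, −0.7); noise_sd 0.7; baselines N(6, 2). The large cohort is
unpaired, n = 499, activity a_s ~ N(0, 1). The small cohort is paired,
n = 19 with 8 designated high and 11 low foci: because such foci are
*selected* by marker immunohistochemistry, their planted activity is
bimodal (separation 3, within-group SD 0.5) with a shared per-patient
baseline shift (SD 0.5). The generator emulates the covariance structure
the analysis assumes — it does not emulate count noise, library-size
variation, batch effects, or correlated gene–gene structure beyond the
single factor, so passing end-to-end tests demonstrates that the pipeline
recovers planted structure under its own assumptions, not that it is robust
to real-data artifacts.

**ChIP.** 60 peaks on one chromosome with lognormal heights and ~400 bp
widths, emitted as 25 bp bins with Poisson counts at 50× expected depth.
Knockdown scales all heights by γ = 0.7 and the designated target
additionally by φ = 1.3 (three knockdown conditions, mirroring a
three-hairpin design); spike-in read counts are Poisson around 10⁵ per
condition. At these depths the planted φ is recovered within ±5% over 20
replicates, and spike-in normalization recovers γ. A second scenario with
φ = 1/1.17 models a positively regulated target whose share falls under
knockdown.

Problem sizes (2,000 genes, 60 peaks, 1,000 permutations) are scaled so the
full study runs in seconds while keeping every statistical contrast
comfortably powered; they are the package's default study conditions, not
claims about any external dataset's size.

## Numerical and design choices

- Gene identifiers are matched by exact string comparison after
  uppercasing; no alias resolution.
- log₂ CPM pseudocount defaults to 1 (configurable); with pseudocount 0 the
  transform is exactly invariant to uniform per-sample count scaling.
- Seeds are mandatory for every stochastic operation; there is no global
  random state, and identical config + seeds reproduce reports bit-for-bit.
- The report schema is a pydantic model; `report_schema.json` is its
  exported JSON Schema and the shipped validation artifact.
- The spec'd command surface (`simulate | score | stratify | diffexp |
  intersect | gsea | correlate | chip | run`) is provided by the library
  functions plus the numbered analysis drivers; this is an analysis
  artifact, not a shell tool, so no console entry point is installed.

## Known limitations

- ssGSEA raw scores carry the random-set offset discussed above; compare
  scores, not their sign against zero.
- The unpaired Welch contrast ignores the paired cohort's within-patient
  correlation; with strong patient effects this is conservative for
  between-focus contrasts within patients and anticonservative across.
- GSEA uses phenotype permutation only (no gene-tag permutation mode) and
  reports no leading-edge genes.
- The occupancy module consumes peaks and coverage; peak calling, read
  alignment and duplicate handling are upstream and out of scope.
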