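# bloodlens

Whole-blood transcriptome analysis of ischemic heart disease cohorts.

`bloodlens` re-implements, as a reusable and tested pipeline, the analysis
chain used to characterize **INOCA** (ischemia with non-obstructive coronary
arteries — a positive stress test with no angiographic stenosis ≥20%) against
controls and CAD from bulk blood RNA-seq:

1. **Differential expression** — DESeq2-style median-of-ratios normalization
   and a per-gene negative-binomial Wald test, with the standard DEG filter
   (uncorrected p < 0.05 and fold change strictly > 1.5, or Bonferroni mode).
2. **Cell-type attribution** — two complementary reads against an immune
   reference atlas (e.g. a Human Protein Atlas blood-atlas export of ~19
   immune cell types): (A) average the atlas expression of the up- and
   down-regulated DEGs per cell type; (B) ignore the DEGs and track
   cell-type-exclusive marker panels in the cohort, flagging any cell type
   whose marker score moves more than 20%. Combining both distinguishes a
   **per-cell expression shift** (the DEGs sit in a cell type whose abundance
   did not move) from an **abundance shift**.
3. **Correlation clustering** — all pairwise Spearman correlations between
   DEGs across patients, hierarchical clustering on distance 1 − ρ, cluster
   annotation by dominant cell type, and inter-cluster net correlation.
4. **Signature comparison** — exact hypergeometric overlap between two DEG
   lists (with discordant-direction genes reported), generic hypergeometric
   over-representation against GMT gene sets, fold-change concordance between
   two groupings, infection-biomarker panel scoring, and sex-stratified
   medians.
5. **Synthetic cohorts** — a generator that builds reference atlases with
   planted cell-type-exclusive markers and draws bulk cohorts as
   negative-binomial cell-type mixtures under null, abundance-shift and
   expression-shift scenarios, with full ground truth. Every stage of the
   pipeline is testable without downloading anything.

## Model sketch

Counts K<sub>gs</sub> for gene *g* in sample *s* are modelled as
NB(μ<sub>gs</sub>, φ<sub>g</sub>) with Var = μ + φμ². Size factors are
median-of-ratios: the reference is the per-gene geometric mean over samples
(genes containing zeros excluded) and s<sub>j</sub> is the median of
K<sub>gj</sub>/ref<sub>g</sub>. The DE test fits, per gene,

```
log mu_gs = log s_s + beta0_g + beta1_g * x_s        x_s = 1 for case samples
```

with dispersion from a method-of-moments estimate shrunk 50/50 toward a
fitted mean–dispersion trend φ(μ) = a/μ + b, and reports the two-sided
normal Wald p for β₁. Fold changes are printed in the signed convention
(+r for r ≥ 1, −1/r otherwise) from pseudo-counted group mean normalized
counts (nRC).

The synthetic mixture model is x<sub>gs</sub> ∝ Σ<sub>c</sub> π<sub>sc</sub> ·
ref<sub>cg</sub> · reg<sub>cg</sub>, where π are cell-type proportions, ref
the atlas, and reg a per-cell regulation factor for perturbed genes.
Abundance scenarios multiply the target type's mixing fraction (then
renormalize); expression scenarios set reg > 1 on the target type's
exclusive markers so the bulk fold ≈ the per-cell fold.

## Worked example

Simulate a cohort in which memory-B cells double the per-cell expression of
10 of their exclusive markers (abundance unchanged), then run the pipeline:

```bash
cat > spec.yaml <<'YAML'
kind: expression_shift
target_cell_type: memory_b
per_cell_fold: 2.0
perturbed_gene_count: 10
n_per_group: 20
dispersion: 0.1
seed: 42
YAML
bloodlens simulate --spec spec.yaml --out sim/
bloodlens run --counts sim/counts.tsv --meta sim/meta.tsv --atlas sim/atlas.tsv --out report/
# pipeline complete: 15 up / 0 down DEGs; reports in report/
```

`report/deg_filtered.tsv` holds the called DEGs (the planted markers land at
signed folds near +2, e.g. `G00112  log2FC 0.978  signed_fc 1.97  p 3.2e-13`),
and `report/verdicts.tsv` the per-cell-type conclusion:

```
cell_type   verdict            attribution_hit  p_vs_pbmc    pct_change  abundance_flag
memory_b    expression_shift   True             0.000977     -7.27       False
mait_t      none               False            NA            3.95       False
```

Reading: the up-regulated DEGs are most expressed in memory-B cells (rank 1,
significant vs. the aggregate total-PBMC reference), while the independent
memory-B marker panel moved only −7.3% between groups — well inside the 20%
band — so the change is called a per-cell expression shift, not a change in
cell numbers. That is exactly the inference pattern the pipeline is built to
automate.

Other subcommands: `bloodlens de`, `attribute`, `cluster`, `compare`,
`ora`, `panels` — each a thin wrapper over a library function, all writing
TSV with floats at 6 significant digits.

## Not in scope

FASTQ/BAM processing and alignment, GEO downloading, proprietary pathway
analysis (IPA), regression-based deconvolution, and plotting beyond basic
helpers.
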