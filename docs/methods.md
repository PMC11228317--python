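# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions — the decisions a maintainer would
otherwise have to reverse-engineer from the code.

## Differential expression

**Normalization.** Median-of-ratios size factors: the per-gene reference is
the geometric mean over samples, restricted to genes with strictly positive
counts everywhere; each sample's factor is the median over those genes of
count/reference. Factors are defined up to a common constant, so the
meaningful invariants are relative: scaling one sample's counts by *c*
multiplies its factor by *c* relative to the others and leaves relative
normalized counts (nRC) unchanged. If no gene is positive in all samples the
estimator is undefined and we raise rather than silently falling back.

**Test.** Per-gene NB GLM with log link on a two-level group indicator and a
log size-factor offset, fitted by IRLS vectorized across genes (the design
is shared, so each iteration solves a closed-form 2×2 system per gene).
Dispersion φ (variance μ + φμ²) comes from a method-of-moments estimate on
normalized counts — pooled within-group variance, corrected for the mean
inverse size factor, floored at 1e-8 — shrunk 50/50 toward a least-squares
trend φ(μ) = a/μ + b fitted over genes with mean nRC > 1. This is a
deliberate simplification of full empirical-Bayes dispersion machinery: it
is transparent, fast, and its calibration is tested directly (on null
cohorts of 5,000 genes at 20 vs 20 and φ = 0.1 the fraction of Wald
p < 0.05 sits near 0.05 and the KS distance from uniform near 0.01). A
cross-check test runs the reference DESeq2 implementation (pydeseq2) on a
small simulated cohort and requires rank agreement of p-values and sign
agreement of strong fold changes; the reference is never used as the
implementation.

**Conventions.** Genes with all-zero counts get p = 1 and log2FC = 0; genes
with fewer than 3 nonzero samples are flagged untested (p = NA) because the
moment dispersion estimate is unusable there. Adjusted p-values (Bonferroni
and BH, both always reported) are computed over tested genes only. The
reported log2FC and signed fold derive from group mean nRC with a 0.5
pseudo-count — finite for zero-count groups and sign-consistent with each
other by construction — while the Wald statistic uses the GLM coefficient,
which is kept in a separate `wald_log2fc` column. The DEG filter is strict:
p < 0.05 **and** |signed fold| > 1.5; in Bonferroni mode the adjusted p is
thresholded and the fold criterion is ignored.

**Nonparametrics.** The per-gene Mann-Whitney U is two-sided,
tie-corrected, exact for small untied samples, and reported as
min(U₁, U₂); a pooled sample with no variation at all returns p = 1 by
convention.

## Cell-type attribution and the verdict

Approach A averages the atlas expression of the mapped up- and
down-regulated DEGs per cell type (directions separately, since they may
represent different cell types); unmapped transcripts are counted, never
imputed. Significance against the aggregate reference is a paired two-sided
Wilcoxon signed-rank over the mapped transcripts' (cell-type − total-PBMC)
differences; this test is our documented choice — the analysis it mirrors
marks significance without naming a test. Zero differences are dropped and
fewer than 5 informative pairs returns p = 1 (the exact two-sided signed-rank
minimum at n = 5 is 0.0625, so nothing smaller is decidable at 0.05). The
total-PBMC reference is the atlas's own aggregate row when present, else the
unweighted mean over cell types (the source atlas does not state weights).

Approach B selects, per cell type, the top-k genes by enrichment =
expression in the type / highest expression among the *other* specific
types (k = 10, minimum enrichment 4, ties broken by gene id, the aggregate
row excluded from the denominator — the denominator is the next-highest
single type, matching how blood atlases describe markers such as PI3 at
1,024× in neutrophils). The panel score is the mean marker nRC per sample,
then per group; the percent change of case vs. control flags an abundance
shift when strictly beyond 20%. In the pipeline the panels additionally
exclude the current DEG list, keeping the abundance audit independent of
the differential signal it judges; note this exclusion conditions the
surviving markers on downward noise, so the closed-form abundance
arithmetic is checked on unexcluded panels.

The verdict per cell type: `abundance_shift` when its panel is flagged;
`expression_shift` when it is top-2 by attribution mean with p < 0.05
vs. total-PBMC (either direction) and not flagged; `none` otherwise. The
flag deliberately takes precedence: a genuine abundance change also drags
its transcripts into the DEG list.

## Correlation clustering

Spearman ρ between all DEG pairs across patients (average ranks for ties);
a constant gene is assigned ρ = 0 against everything, logged. Distance is
1 − ρ, **not** 1 − |ρ|: positively and negatively correlated transcripts
must not merge, because the sign of inter-cluster correlation (e.g. an
invariant-T cluster anticorrelated with a neutrophil cluster) is part of
the biology being read out. Linkage is average by default (standard for
correlation heatmaps), cut either into k clusters or at a height (default
0.6, i.e. within-cluster ρ ≳ 0.4 — a documented guess exposed in config,
since no cut criterion is given by the analysis this mirrors). Cluster ids
are renumbered in order of first appearance so the partition is stable
under gene permutation. Cluster labels are the modal primary cell type
(argmax atlas expression) of the member genes, requiring a strict majority;
exactly half is "mixed".

## Overlap, ORA and panels

Hypergeometric upper tails are accumulated from log-pmf terms via
log-sum-exp, so tails of order 1e-22 (a 23-gene overlap of 199- and
181-gene lists in a 28,000-gene universe) evaluate without underflow; the
implementation is tested against exhaustive enumeration for every
configuration with N ≤ 12. The default universe is the number of genes
tested by the DE stage, overridable (including a fixed value such as the
~28,000 transcripts a whole-blood run quantifies). Discordant overlap genes
are those whose log2FC signs differ with both beyond a ±0.05 dead zone —
the dead zone avoids labeling noise-level flips as discordance. ORA is
one-tailed over-representation only, BH-corrected over tested sets.
Fold-change concordance reports both Spearman and Pearson, since the
appropriate scale is a judgement call. Panel scoring reports mean (sd) nRC
per group and an uncorrected Mann-Whitney p against the reference group for
each other group; stratified medians report each stratum's per-gene median
as a percent of the reference stratum (NA when the reference median is 0).

## Synthetic cohorts

The generator emulates: ~19 immune cell types with planted cell-exclusive
markers; bulk counts as NB-noised mixtures; library sizes log-normal
(σ = 0.2) around the mean to exercise size-factor estimation, mirroring
the spread of real per-patient read depths; and three scenario families
(null, abundance shift with renormalized mixing fractions, per-cell
expression shift on exclusive markers so bulk fold ≈ per-cell fold, plus a
combined mode and a shared-gene flag for harder attribution cases).
Defaults are the study-like conditions used throughout the tests: 19 types,
2,000 genes, 20 markers per type, marker enrichment 1,024 (the printed
magnitude of top neutrophil markers; this makes markers effectively
cell-exclusive, the regime where marker averaging reads out abundance and
where the closed-form +42.9% arithmetic for a ×1.5 shift at base fraction
0.10 applies), baseline mean 5 with log-normal σ = 1, dispersion φ = 0.1,
20 samples per group, and a median library of 1e6 reads for 2,000 genes
(≈500 reads/gene, the per-gene depth of ~15M reads over ~28,000
transcripts; the 5,000-gene calibration and recovery runs use 2.5e6 for
the same depth). Proportions are neutrophil-dominant (50%) as in whole
blood, uniform otherwise.

What the generator does **not** emulate: real atlas expression values,
correlated gene-gene noise within cell types, patient covariates
(age/BMI/medication), batch effects, or compositional interactions between
multiple simultaneously shifting cell types. Passing tests therefore
demonstrate that the inference machinery is correct under its own model
assumptions — calibrated nulls, recoverable planted effects, correct
verdict logic — not that real cohorts satisfy those assumptions.

## Problem sizes and numerics

The test-suite and acceptance-script simulations use 5,000 genes for
calibration/recovery and 2,000 genes × 60 cohorts for scenario
discrimination; these sizes give stable statistics while keeping a full run
in well under a minute for the script. Floats in output TSVs are printed at
6 significant digits with NA for missing; all tables have fixed column
order, and the pipeline is byte-deterministic given its inputs and
configuration. IRLS runs at most 50 iterations with linear predictors
clipped to ±30 and a 1e-10 convergence tolerance. Gene identifiers are
matched by exact, case-sensitive string comparison everywhere; a synonym
table hook exists but ships empty.

## Known limitations

- The dispersion estimator is moment-based with a simple trend; at very
  small group sizes (n ≲ 5 per group) the Wald test will be less well
  calibrated than full empirical-Bayes machinery.
- No covariate adjustment or interaction terms in the DE model.
- The attribution significance test and the cluster cut height are
  documented choices, not reproductions of the original analysis's
  (unstated) procedures.
- Marker-based abundance reading assumes near-exclusive markers; with
  weakly enriched markers (≲10×) an abundance shift is attenuated toward
  the flag threshold and discrimination degrades.
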