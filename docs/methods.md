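# Methods

This note documents the models, statistics, defaults and design choices
behind `agingtx`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All intervals are 0-based half-open (standard BED); the TSS of a
`+`-strand gene is its `start`, of a `-`-strand gene its `end`. Peak files
are BED3/BED6 with an optional 7th column holding the summit offset
relative to `start`; absent a summit column, the summit defaults to the
interval midpoint (public peak dialects vary in whether they carry a
maximum-read-density position; the midpoint is the neutral fallback).
Counts, designs, gene models and gene sets are TSV with a commented
provenance header recording tool version and parameters.

## Regulator-enrichment screen

*Replicate consistency.* A peak is retained iff it overlaps (≥ 1 bp) a
peak in the other biological replicate; the retained interval is the union
of the overlapping intervals and the summit is taken from the
higher-scoring peak (replicate 1 on ties). Only replicate-consistent peaks
enter the screen.

*Complexity filter.* The complexity score of a peak is the number of
distinct **other** factors (stage-matched datasets only; the focal factor
is never counted) with ≥ 1 bp overlap. Peaks with score ≥ `complexity_max`
(default 8) are discarded as HOT sites. "Bound to the same site" is
operationalized as interval overlap; multiple peaks from one factor count
once. The panel-wide scorer indexes intervals per (stage, chromosome,
factor) as sorted starts with prefix-maximum ends; a per-dataset
intervaltree implementation is kept as the reference and the two are
cross-checked in the tests.

*Target assignment.* Assignment uses the peak **summit**: a gene is a
target iff some summit lies in `[TSS−w, TSS)` (`+` strand; mirrored for
`-`; `w` = 5000 bp) or inside the gene body `[start, end)`. A peak whose
interval but not summit enters a window does not assign; one summit may
assign to several genes.

*Enrichment.* A 2×2 chi-square (1 df, no Yates correction by default; a
flag enables it) on target × age-set membership over the universe of all
annotated genes. Back-solving the published 2.1-fold from the printed
overlap counts implies a universe of ≈ 20,000 genes (the *C. elegans*
protein-coding complement), which is what the worked example uses; the
universe is always an explicit argument. Expected cells < 5 are flagged
(`low_expected`) but still computed. The Bonferroni threshold divides the
family α (0.05) by the number of datasets actually screened; the screen
cutoff additionally requires fold ≥ 1.5 and p < 10⁻⁵. Ranking is by
ascending p, then descending fold, then dataset id, so reports are
deterministic.

## Rank-product differential expression

Counts are normalized per sample as `(count + pseudocount) / Σ(count +
pseudocount)` with a 0.5-read pseudocount so all folds are finite. For a
treated/control contrast, a fold change is formed for every treated ×
control sample pair (the published rank-product convention for unpaired
biological replicates; `paired=True` switches to index-paired replicates).
Within each comparison genes are ranked by fold, ascending for the down
direction and descending for up, with average ranks on ties; RP is the
geometric mean of the ranks.

The permutation null shuffles gene labels independently within every
comparison's fold vector (equivalently: permutes each comparison's rank
column). With P permutations pooled over n genes:

    p(g)   = (#{null RP ≤ RP_g} + 1) / (nP + 1)
    pfp(g) = (#{null RP ≤ RP_g} / P) / rank(RP_g)

pfp is reported unclipped; calls use pfp ≤ cutoff (default 0.10), and a
gene passing both directions takes the direction of the smaller pfp. An
exhaustive mode enumerates all within-comparison permutations for tiny
problems and is used as the test oracle.

*Calibration caveat (documented, inherent to the scheme).* All-pairs
comparisons share samples, so the observed fold vectors are correlated
across comparisons while the permutation null treats them as independent.
The result is anti-conservative: on complete-null 3v3 data ≈ 11% of genes
are called at pfp ≤ 0.10, and the per-gene p has inflated tails (≈ 13% at
p < 0.05). With a single comparison, or with paired comparisons (disjoint
samples), the permutation null is exact and both quantities are
calibrated; the parameter-recovery analyses therefore use paired mode,
while the null-rate property is asserted for the default all-pairs mode.
Default 100 permutations balances runtime against pfp stability at the
10% cutoff.

## Cross-stage classes

For genes FDR-called at one stage, membership in the *general* class
requires a same-sign change at the other stage with p < 0.05; otherwise
the gene is *establishment* (L1-called) or *adult* (L4-called). The
concordance p is the rank-product permutation p of the direction the gene
moved at the other stage (the classification rule only needs "a
significant concordant change"; the statistic behind it is swappable).
Genes called at both stages with opposite signs get a dedicated
*discordant* label rather than silently joining a stage-specific class;
genes missing from one stage's measurements are *unclassified*.
Percentages are over the three named classes and rounded half away from
zero (103/61/59 of 223 → 46/27/26).

## Attenuation slope

Gene filtering, in this order: (1) keep genes with raw depth ≥ 10 in at
least one library of either condition; (2) drop the union over libraries
of each library's top 3% most-expressed genes (under shared-fraction
normalization, differential behaviour of a few very large genes would
otherwise distort every other gene's fraction). The per-stage gene counts
are recorded so a reordering would be detectable.

Per replicate (control and test paired by replicate index), per-gene
log₂(old/young) ratios are computed on fraction-normalized counts and the
test ratios are regressed on the control ratios by OLS **with intercept**
(the slope interpretation is unchanged; the intercept absorbs uniform
offsets and is reported). Each fit reports slope, intercept, R², and
t-tests of slope = 0 and slope = 1. R² equals the squared sample
correlation (asserted to 10⁻¹⁰ in tests). Replicate slopes are averaged;
the 95% CI and the test against 1 use the t distribution on the replicate
slopes (n−1 df) — consistent with reporting a mean ± CI ± p triple over
five biological replicates. Identical slopes across replicates collapse
the CI to a point with a degenerate-variance warning. Tissue-restricted
variants rerun the same regression on tissue gene lists (tissues with
< 20 usable genes are flagged, not fitted); `compare_conditions` applies
the same OLS to two independent aging programs and reports slope and R²
(an unrelated program gives R² ≈ 0).

Because both axes carry measurement noise, OLS of test on control is an
errors-in-variables regression and is attenuated by
var(noise)/var(signal). This is a property of the estimator (the field's
standard for these scatterplots), not of the implementation; the synthetic
defaults keep the ratio ≲ 0.5% so the bias (< 0.01 in slope units) is
negligible against the replicate-level CI.

## Trajectory utilities

Baseline normalization returns log₂ ratios to the first timepoint
(replicate columns averaged, on the given scale, before ratio formation);
it is idempotent on already-normalized input. Sign concordance excludes
genes with a zero change in either vector (concordance is defined only by
sign) and tests the concordant count with a one-sided exact binomial
against 0.5 — the choice of test is the package's own; published
concordance p-values from other tools are close but not asserted equal.
K-S comparisons use the standard two-sample two-sided statistic with the
asymptotic p.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the shape of the study the pipeline was built for;
all sizes and rates are configurable, and the defaults below are the
package's choices (no noise magnitudes are published for any of the
emulated datasets; they were calibrated once so that parameter-recovery
properties are discriminating, and are not tuned per run).

* **Annotation** — genes tiled at fixed pitch (2 kb genes, 8 kb gaps) on 6
  chromosomes, alternating strands; deterministic. A margin at each
  chromosome end is reserved for replicate-private noise peaks.
* **ChIP panel** — 99 datasets over 58 factors by default (every factor at
  L1, the surplus at L4). Hot sites (60, placed at L1 where every factor
  is present) receive peaks from 12 factors each, so they exceed the
  complexity threshold and must be removed by the filter; each factor gets
  250 specific peaks whose summits fall in the near-upstream 2.5 kb of
  target genes (inside exactly one gene's assignment region at the default
  spacing, so the planted target list is exact). The planted factor's
  targets overlap the age set (200 of 2000 genes) at a configured fold of
  the hypergeometric expectation (default 2.1). Both replicates carry
  every true peak with ±25 bp jitter plus 10% replicate-private noise
  peaks on disjoint lattices in the reserved margin, so noise can never
  survive replicate intersection.
* **Counts (RNAi contrasts)** — negative binomial (Var = μ + φμ²) with
  log-normal gene means (ln-scale mean 5, sd 1.5), dispersion φ = 0.05,
  library sizes jittered ±20%. Planted DE genes multiply the treated mean
  by 2^(±lfc) at the stages their class dictates (both / L1-only /
  L4-only). The L1-experiment preset plants 153 down + 9 up at L1 with
  lfc 2.5 and φ = 0.02 (near-complete knockdown of direct targets, deep
  pooled 3′-tag libraries).
* **Aging timecourse** — each gene carries a true control aging effect
  r_g ~ N(0, 1.2²) on the log₂ scale, with a 15% strongly age-regulated
  subset at sd 2.5; the overexpressor's true effect is α_tissue(g)·r_g
  (defaults: intestine 0.85, muscle/hypodermis/neurons 0.90, germline
  1.0, other 0.87). Each of the 5 replicate cohorts shifts all its alphas
  by a common N(0, 0.03) draw — replicate populations age at slightly
  different rates, which is what gives the replicate-t CI a real variance
  component. Observed ratios add N(0, 0.05) per-replicate noise and are
  back-transformed through the NB model at deep coverage (40M reads per
  library, φ = 0.0005, ln-sd 1.0), keeping the errors-in-variables slope
  bias below 0.01.

What it does **not** emulate: sequence-level structure (reads, motifs, GC),
realistic chromosome sizes, batch or lane effects, correlated gene
programs, microarray-platform noise, or count-level dependence between
the RNAi and timecourse experiments. Passing recovery tests therefore
demonstrate correctness of the statistics under the stated generative
model, not robustness to every artifact of real libraries.

All `simulate_*` functions draw from `default_rng(seed + stage_offset)`
with fixed per-stage offsets, so outputs are byte-identical across runs
and adding one stage never perturbs another's draws. Problem sizes used by
the shipped property checks (e.g. 7,000-gene timecourses, 50-dataset
screens, 200 null DE simulations at 500 genes) are the package's desk
scale defaults and are stated in the tests themselves.

## Pipeline

`run_pipeline` executes simulate → screen → de → classify → slope →
trajectory in dependency order with pre-flight validation that lists every
problem at once. One global seed fans out to per-stage seeds by stable
offsets. The JSON run report records tool version, per-stage parameters,
input checksums, row counts, key statistics and wall-clock times;
re-running the same config and seed reproduces every output byte (only
timings differ).
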