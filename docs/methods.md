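# Methods

## Conservation scoring

The conservation score of a gene is CS = −ln(dN/dS), natural logarithm,
computed only for genes where the ratio is informative. Exclusion rules, in
decreasing precedence: non-one-to-one orthologs, paralog-bearing genes,
dS = 0 (infinite ratio), dN = 0 (zero ratio), and dN/dS ≥ 0.8 (putative
positive selection; the threshold is closed, and the comparison carries a
1e-12 relative tolerance so that ratios that are exactly 0.8 in real
arithmetic, e.g. 0.08/0.10, land on the boundary despite floating-point
rounding). When several rules apply, only the highest-precedence reason is
recorded: orthology problems make the ratio meaningless before its value
does. Inputs that ship a precomputed ratio without separate dN and dS (an
`omega` column via the reader's dialect map) skip the zero-dN/zero-dS checks,
which cannot be evaluated, but still receive the 0.8 cutoff — applied
uniformly because there is no principled reason to exempt such inputs.

The relative conservation score RCS_i = CS_i − MCS_constant centres CS on the
arithmetic mean score of the dataset's constantly expressed genes; the mean
RCS over that anchor set is 0 by construction (checked to 1e-12).

## Normalization

Median-of-ratios size factors: the reference for gene *g* is the geometric
mean of its counts across samples (computed in log space), taken over genes
strictly positive in every sample; sample *j*'s factor is the median of
counts_gj / reference_g. The zero-tolerant "poscounts" variant is not
implemented — if no gene is positive everywhere the estimator stops with an
error asking for pre-filtering rather than silently switching method. After
division by the factors, genes expressed in no sample are dropped.

## Age-bias classification

Per-gene Spearman correlation between expression and age uses average ranks;
two-sided p-values use the t approximation with n − 2 degrees of freedom,
which is adequate at the sample sizes this pipeline targets (≥ 10); exact
permutation p-values are deliberately not offered. Three modes:

- **bulk**: age-related iff BH-adjusted p < 0.1 and |rho| > 0.5 (alternative
  cutoffs 0.3 / 0.7 supported for sensitivity analyses);
- **single_cell**: |rho| > 0.5 only — pseudobulk series over a handful of
  individuals are too noisy for the significance gate to be useful;
- **sign_only**: the sign of rho alone, for unreplicated designs; with two
  samples this reduces to the sign of the expression difference, ties giving
  "constant".

"Constant" is a residual category: genes failing either gate, including flat
genes whose rho is undefined. Ages enter in whatever unit the dataset uses
(days, weeks, months); only ranks matter, which is tested explicitly.

## The ADICT statistic

Per unit (sample, or cell-type × individual pseudobulk), ec_rho =
Spearman(expression, CS) across genes — at least 3 shared genes required.
ρ_ADICT = Spearman(ec_rho, age) across units, at least 3 units; if ec_rho is
constant across units the result is flagged degenerate rather than forced to
zero. Profiles can be restricted to the dataset's own age-classified (DE)
genes — the union of old- and young-biased genes classified from that same
dataset, not an external list — which concentrates the signal.

Class comparisons use Welch's two-sided t and the two-sided Mann–Whitney U
(normal approximation with continuity and tie correction; exact enumeration
when both groups have ≤ 8 genes). Bootstrap CIs for mean RCS are percentile
intervals over B = 1000 resamples of genes with replacement — percentile
rather than BCa because nothing in the analysis depends on second-order
accuracy and the percentile interval is the simplest defensible choice. A
seed is a required argument for every resampling operation.

The confound model is an OLS fit of raw dN/dS (not CS — the response is the
ratio itself) on expression level (mean or max variant), gene age in Myr, and
a binary old-biased indicator; constant or collinear predictors raise an
error naming the predictor.

## Cell-type analysis

Pseudobulk is the per-gene arithmetic mean over an individual's cells of one
type, per tissue; the pipeline is unit-agnostic about what the per-cell
values are, provided they live on a linear scale so the mean is meaningful.
Filtering is fixed-order and deterministic: first cell types absent from any
required age group are removed (within tissue), then, within each tissue ×
age group, individuals covering ≤ 70% of the tissue's remaining cell types
are dropped (">70%" is strict: 7 of 10 fails, 8 of 10 passes).

Cross-cell-type profiles use the common gene set — the intersection of genes
expressed in every tissue of the run, computed **after** filtering (the
alternative ordering is not identifiable from the analysis description; the
set size is logged). Cell types with fewer than three individuals are
excluded ("less than three" excludes n = 2). The cell-type decomposition is a
sequential (type-I) ANOVA, tissue entered before cell type; the immune-status
test is a linear mixed model with a random tissue intercept (REML), falling
back to one-way ANOVA with a logged warning when only one tissue is present.
With few tissues the random-effect variance often sits on the boundary and
statsmodels emits a convergence warning; the fixed-effect estimate is still
valid and is what is reported.

Per-cell-type ADICT classifies genes per cell type in single-cell mode and
profiles that cell type on its own DE genes; if fewer than three genes
classify, the profile falls back to all scored genes and records
`gene_set_used = whole_transcriptome`. BH correction is applied within
tissue by default (a flag pools across tissues), and cell types shared by
several tissues are evaluated per tissue.

## Immune contributions

MRCS reports give mean RCS of old- and young-biased genes per cell type,
with mrcs_diff = young − old; the paired comparison across cell types within
a tissue is an exact two-sided Wilcoxon signed-rank test (warning below five
pairs; all-zero differences report p = 1 with a flag). Immune vs non-immune
cell-type comparisons collapse repeated cell types to their cross-tissue
mean, then apply the two-sided Mann–Whitney test and Cohen's d with the
pooled-variance denominator (n1 + n2 − 2 df).

Overrepresentation odds ratios: within a cell type's expressed, scored genes
(not genome-wide — this matches the per-cell-type contingency context and is
logged so the alternative is auditable), the bottom and top conservation
quartiles are delimited by linear-interpolation quantiles with inclusive
thresholds (cs ≤ Q25 is "low-conserved", cs ≥ Q75 "high-conserved"). Among
old-biased genes the low-conserved tail is crossed with immune membership;
among young-biased genes the high-conserved tail. The sample odds ratio is
ad/bc (0 or ∞ on a single zero cell; any zero margin is flagged degenerate
with no p-value), the test is the two-sided Fisher exact test, and BH runs
across cell types within each direction. At least 20 classified genes per
direction are required.

## Tajima's D

Windows are tiling and non-overlapping, span = step = 10 kb, 0-based
half-open; VCF 1-based positions are converted by subtracting 1. Per window,
S is the number of segregating biallelic sites, π = Σ 2j(n−j)/(n(n−1)) over
alternate-allele counts j, and D = (π − S/a1) / sqrt(e1·S + e2·S(S−1)) with
the standard constants derived from the haplotype sample size n. D is
undefined (missing, never 0) when S = 0. π and S are folding-invariant, so no
ancestral-allele polarisation is needed. Sites with any missing genotype are
dropped with a logged count — simpler than per-site sample-size rescaling and
adequate at the scales this package targets.

Gene-wise D is the mean of overlapping window D values weighted by the CDS
overlap length in base pairs, summed over a gene's (possibly many) CDS
intervals; only windows with defined D contribute. The weight definition is
an interpretation — overlap length is the only quantity available to both
windows and genes — and is recorded in the output metadata. Class comparisons
are two-sided Mann–Whitney per population plus a pooled row (per-gene mean D
across populations).

## The synthetic-data generator

The generator emits every input format the pipeline reads and is itself
tested code. What it emulates, and the defaults that define the study
conditions:

- **Bulk**: five unequal adult ages with three replicates each (ages in
  weeks: 8, 26, 52, 78, 104), deliberately tied so rank handling is
  exercised; 20% old-biased and 20% young-biased genes with ±0.05/week
  centred log-expression slopes; Gaussian log-scale noise (sd 0.3); Poisson
  counts (an optional negative-binomial dispersion knob exists) around
  per-sample depth factors log-uniform in 0.5–2×, so the normalizer always
  has real work to do. ln(dN/dS) is Normal(−1.5, 0.5) — median ω ≈ 0.22,
  roughly 80–90% of genes under the 0.8 cutoff, matching the regime the
  scoring rules assume — with the class coupling planted as ±coupling/2
  shifts on ln ω, so the expected CS difference between classes equals the
  coupling (default 0.4) exactly.
- **Single cell**: two tissues × four cell types by default, one immune type
  per tissue; cell-type identity is expressed through a per-type
  `conservation_affinity` that tilts the type's baseline profile toward high-
  or low-CS genes (this field is what makes cell types differ in
  transcriptome conservation, and is required for the composition-confound
  scenario); multinomial cell counts per individual with age-dependent
  proportions; optional per-type cell-autonomous coupling that raises
  low-CS-gene expression with age within the type. Values are linear-scale
  exponentiated Gaussians.
- **Variants**: per-window S ~ Poisson(θ·a1) with allele counts ∝ 1/j
  (neutral) or with the singleton class inflated 3× (singleton_excess);
  synthetic genes tile windows with known overlaps, including two-exon genes
  split 3 kb / 7 kb across window pairs.

What it does **not** emulate: overdispersion beyond the optional NB knob,
batch effects, scRNA-seq dropout beyond Poisson-like sparsity, linkage
between sites, realistic demography, or shared individuals across tissues.
Passing tests therefore demonstrate that the statistics recover what was
planted under clean sampling noise — not that real data meet these
assumptions.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale by choice: null calibration uses
1,000 replicates of a 1,000-gene × 15-sample design; effect recovery 200
replicates at 5,000 genes; the composition-confound contrast 100 replicates
of a 3-type, 400-gene, 60-cells-per-individual design; bootstrap coverage
500 gene sets of 200 genes with B = 1,000. Scaling genes or cells up changes
runtime, not recovery rates, beyond sampling error.

Known limitation observed in the confound scenario: a cell type whose share
of cells shrinks with age gets noisier pseudobulk means, which attenuates
its expression–conservation correlation toward zero; when types differ in
their baseline correlation this attenuation can impart a small negative
drift to per-cell-type ADICT even without any cell-autonomous change. At the
default cell counts the per-type mean rho stays within ±0.1 of zero while
the mixture-level ADICT is strongly negative, so the contrast the scenario
exists to demonstrate is unaffected; more cells per individual shrink the
drift.

Degenerate inputs are errors, not silent defaults: empty tables, all-zero
reference sets, single-level ANOVA factors, constant predictors and
sub-minimum group sizes all raise typed exceptions that the CLI maps to
exit codes (2 configuration, 3 input, 4 analysis). All resampling takes an
explicit seed; workflow bundles contain no timestamps and re-run
byte-identically under the same config and seed.
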