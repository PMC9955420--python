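# Methods

## Array normalization

Background subtraction is elementwise foreground − background on the raw
scale, clipped below at a floor (default 1.0 raw unit) so the subsequent
log2 transform is defined. Subtraction precedes the log transform; this
ordering is fixed and documented here because array-processing packages
differ on it.

Cyclic loess normalization operates on the log2 matrix: for every sample
pair (visited in lexicographic sample-ID order, for determinism) a lowess
curve of M = x_i − x_j on A = (x_i + x_j)/2 is fitted across features and
half the fitted trend removed from each sample; the sweep repeats for a
fixed number of iterations (default 2). Defaults: span 0.4, local degree 1
(lowess), two robustifying (bisquare) iterations inside each fit. The
robust fit matters: genuinely reactive spots are large-M outliers
concentrated at high A, and a non-robust fit follows them and normalizes
real signal away. An interpolation shortcut (`delta` = 1 % of the A range,
far below the span) keeps the O(S²) pair sweep fast without visibly
changing the fit.

Properties the tests verify: a constant log2 offset between samples is
reduced > 95 %; a planted M = 0.5·A distortion is reduced ≥ 80 % (measured
by refitting a loess on the output); feature ranks within samples are
preserved (Spearman ≥ 0.95 on null data); a second pass changes values by
< 10 % of the first pass.

## Healthy-control baseline and Z-scores

Per feature, the HC log2 values are screened with the generalized extreme
studentized deviate (ESD, Rosner) test, two-sided, k_max = 3, α = 0.01. At
removal step i the statistic R_i = max|x − x̄|/s is compared to

λ_i = (n − i) · t_{p, n−i−1} / sqrt((n − i − 1 + t²)(n − i + 1)),
p = α / (2 (n − i + 1)),

and the declared outliers are the first j removals for the largest j with
R_j > λ_j — the stepwise structure is what defeats masking by pairs of
similar outliers. Vectors shorter than k_max + 3 are left untrimmed with a
warning rather than rejected, so features with tiny baselines still get a
baseline. Flagged HC subjects are excluded for that feature only; the
remaining values give the baseline mean and SD (n − 1 denominator). The SD
is clipped below at sd_floor = 0.1 log2 units to prevent Z blow-ups on
near-constant features; baselines that would shrink below 5 values fall
back to untrimmed statistics (logged). Z-scores are computed for every
sample, controls included. Trimming operates on normalized log2 input.

## Reactivity statistics

All thresholds are configuration with the published defaults: reactivity
Z > 5 (strict), overlap prevalence ≥ 30 %, count-curve grid 1..10,
top-100-variance heatmap slice, top-4000 rank curves, volcano Z > 1 with
Welch-t p < 0.05 versus HC (no multiplicity correction by default; a BH
column is always reported). Group rank curves aggregate by within-group
median Z. Hierarchical clustering uses Euclidean distance with Ward
linkage; the hot/cold split clusters SLE subjects only (not the full
cohort dendrogram), cuts at 2, and names 'hot' the cluster with the higher
mean Z over the SLE overlap set; an all-identical degenerate input yields
a single all-'cold' cluster with a warning. Subjects with no Z > 5
feature are excluded from the restricted median (logged). PCA is centered,
subjects as observations; component signs are arbitrary.

## Localization

The five-category vocabulary (extracellular, nuclear, cytosolic, membrane,
other) is fixed; the antigen → categories mapping is an input table, with
unknown antigens resolving to {other}. Multi-label antigens count in every
category they carry, so group percentages may sum above 100. Resolving GO
terms to categories is deliberately out of scope — the mapping arrives as
data.

## Expression signature

The IFN gene-signature score is the mean over the panel of per-gene
standardized values (HC mean/SD); IFN-hi means score > mean + 2 SD of the
HC scores. Both the panel (9 interferon-stimulated genes by default:
IFI27, IFI44L, IFIT1, ISG15, MX1, OAS1, RSAD2, SIGLEC1, USP18) and the SD
multiplier are configuration — they are conventions of this package, not
claims about any particular clinical assay. Differential expression is a
per-gene pooled-SD standardized mean difference with a Welch t test,
flagged at |Z| > 0.7 and p < 0.01. Over-representation is a one-sided
hypergeometric tail per gene set with BH-FDR across sets.

## Repertoire metrics

Clonotype = allele-stripped V gene call + exact junction amino-acid
sequence; UMI counts are summed within a clonotype and per-region mutation
counts carried as UMI-weighted means. This definition is a package
convention (stated prominently because clonotype definitions vary).
Gini uses the population mean-absolute-difference form (no n/(n−1)
factor), computed by the sorted O(n log n) identity and clamped at 0
against −1e−17-scale round-off in the exact-equality case. R20 takes
clones in stable descending order; the first clone reaching the 20 %
target counts fully (no fractional interpolation). CDR3 length is
junction length minus the two conserved anchors. SHM input is per-region
mutation counts supplied by upstream annotation (or the simulator);
germline alignment is out of scope. Group tests are two-sided
Mann–Whitney U (midrank ties) with BH adjustment across the comparison
family.

## Synthetic cohort

The generator emulates the four archetypes with planted, recoverable
truth. One master seed feeds named `SeedSequence` children (truth, array,
bcr, expression), so arms regenerate independently and byte-identically.

Array arm: per-feature lognormal baseline (log2 mean ~ N(8, 1), log2 SD ~
U(0.15, 0.35) — typical protein-array dispersion), per-sample scale jitter
(SD 0.15 log2) for the normalizer to remove, and an additive raw
background channel (2^N(4, 0.3)). Planted shifts are expressed in
baseline-SD units: APECED 40 disjoint targets at 12 ± 2 SD, 85 %
prevalence; SjS exactly 2 targets at 10 ± 1.5 SD, 100 % prevalence; SLE
150 targets, hot subjects (50 % of the group) at 8 ± 2 SD / 90 %
prevalence and cold subjects at 3 ± 1 SD / 30 % prevalence; target
localizations are drawn extracellular-biased for APECED and
nuclear/cytosolic-biased for SLE/SjS. HC outliers: round(rate · n_HC)
subjects (default rate 0.1 → 2 of 18) shifted 9 ± 1 SD on a random 3 % of
features — broad enough to exercise per-feature trimming, sparse enough
that robust loess does not erode the signal. Reactive breadth is kept at
a few percent of the array throughout because that is what real
autoantigen arrays show and what loess normalization assumes; per
realization the per-subject outlier-exclusion rate lands around 90–97 %.

Repertoire arm: clone frequencies from a symmetric Dirichlet
(concentration HC 1.0, APECED 0.2, SjS 2.0, SLE 5.0 — the minimal
one-parameter model producing the expanded-vs-even group ordering), 500
clones/subject, multinomial UMI depth 20 000; VH calls from a fixed
long-tailed multinomial over 38 IGHV genes with random allele suffixes
(exercising allele stripping); junction lengths ~ round(N(17, 2)) clipped
to [8, 30] (CDR3 mean 15); per-region mutation counts Poisson with group
total means HC 20, APECED 13, SjS/SLE 14 split over FR1/CDR1/FR2/CDR2/FR3
by length-proportional weights (0.25/0.10/0.15/0.12/0.38). Mutations are
planted as counts, not simulated at nucleotide level, because every
downstream statistic is a count rate. Expanded clones are occasionally
emitted as split records sharing the clonotype key to exercise collapsing.

Expression arm: Gaussian log-expression with unit per-gene SD; the IFN
panel is shifted +5 SD in planted IFN-hi subjects (all hot SLE, 50 % of
cold SLE, 20 % of SjS, no HC/APECED).

What the simulator does **not** emulate — batch effects beyond per-sample
scale, spatial slide artifacts, isotypes other than IgG, nucleotide-level
SHM, count-based expression noise, antigen cross-reactivity — bounds what
green tests mean: they certify the statistical machinery and its planted-
truth recovery, not performance on any clinical cohort.

## Problem sizes and numerical choices

Default desk-scale sizes: 2 000 array features (configurable upward),
500 genes, 500 clones/subject at depth 20 000, cohort 107 subjects.
The end-to-end run (dominated by the O(S²) loess pair sweep) takes about
a minute on one CPU; the demo config (`configs/demo.yaml`) uses a reduced
cohort for a seconds-scale full-pipeline run. Ties in the ESD
maximum-deviation step break by first index; lowess uses two robustness
iterations; hierarchical-clustering leaf orders come from scipy's
dendrogram convention; TSV writers use a fixed float format so reruns are
byte-identical.

## Known limitations

* Per-subject HC-outlier exclusion is strong but not certain (~90–97 % of
  planted features per realization); undetected outlier features inflate
  that feature's baseline SD and shrink everyone's Z there.
* Cyclic loess assumes reactive features are sparse at every intensity;
  cohorts where a large fraction of high-intensity features are truly
  reactive will see signal attenuation even with robust fitting.
* The hot/cold split assumes exactly two SLE strata; intermediate
  phenotypes are forced into one of them.
* Overlap sets use strict Z > 5; features oscillating around the cutoff
  are unstable members near 30 % prevalence.
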