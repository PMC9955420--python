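# autorep

Analysis pipeline for comparing autoantibody repertoires and B-cell
receptor (BCR) repertoires across autoimmune diseases with very different
serological footprints — the monogenic disease APECED (focused, very
high-magnitude autoreactivity), systemic lupus erythematosus (SLE; broad,
weak-to-moderate autoreactivity split into "hot" and "cold" patient
subgroups), Sjögren's syndrome (SjS; a narrow canonical pair of
reactivities), and healthy controls (HC).

It is written for immunologists and biostatisticians who have:

* protein-microarray IgG reactivity tables (features × samples, foreground
  and background channels),
* AIRR Rearrangement TSVs of clonotyped heavy-chain sequences, and/or
* a log-scale gene-expression matrix,

and want the standard repertoire-characterization statistics with a tested,
reproducible implementation.

## What it computes

**Array arm.** Raw intensities are background-subtracted, log2-transformed
and cyclic-loess normalized (robust pairwise MA-trend removal). Each
feature's healthy-control values form a baseline after generalized ESD
(Rosner) outlier trimming at `k = 3`, `α = 0.01`; every subject's Z-score
for feature *g* is

    Z_sg = (x_sg − μ̂_g) / σ̂_g

with μ̂, σ̂ the trimmed HC mean and SD. Downstream: reactivity counts over a
Z-threshold grid (1–10), per-subject median Z, group-ranked reactivity
curves, Welch-t volcano calls versus HC (Z > 1, p < 0.05), group *overlap
sets* (antigens with Z > 5 in ≥ 30 % of a group) with per-subject %
reactivity overlap, top-variance hierarchically clustered heatmap input,
Ward-clustering hot/cold stratification of SLE, PCA, and a multi-label
cellular-localization breakdown of each group's overlap set.

**Repertoire arm.** AIRR records are collapsed to clonotypes
(allele-stripped V gene + junction amino acids, UMIs summed). Per subject:
rank–fraction curves (top 4000 clones), the Gini index of clone frequencies

    G = Σ_i Σ_j |x_i − x_j| / (2 n Σ_k x_k),

R20 (fraction of unique clones holding the top 20 % of repertoire mass),
VH gene usage (top 30), CDR3 lengths (junction − 2 anchors), and somatic
hypermutation load per V-gene region (FR1/CDR1/FR2/CDR2/FR3). Groups are
compared with two-sided Mann–Whitney U tests under Benjamini–Hochberg FDR.

**Expression arm.** An interferon gene-signature score (mean of
HC-standardized panel genes, 9-gene default panel) with IFN-hi/lo
classification at mean + 2 SD of the HC scores, simplified differential
expression (|Z| > 0.7, p < 0.01), and hypergeometric gene-set
over-representation with BH-FDR.

**Synthetic cohort.** `autorep.simulate` generates all three data arms with
planted truth (group archetypes, hot/cold labels, IFN-hi flags, target
antigens, localization, clone-concentration parameters), so the entire
pipeline is testable end-to-end without access data. Default sizes are
HC 18 / APECED 20 / SjS 26 / SLE 43.

## Worked example

```python
from autorep import CohortDesign, generate_bcr_repertoires
from autorep.repertoire import repertoire_summary

tables, truth = generate_bcr_repertoires(CohortDesign(seed=1))
summary = repertoire_summary(tables)
summary["group"] = truth.group
print(summary.groupby("group")[["gini", "r20", "shm_overall"]].median().round(3))
```

```
         gini    r20  shm_overall
group
APECED  0.690  0.026       13.047
HC      0.494  0.051       20.037
SLE     0.259  0.104       14.004
SjS     0.380  0.074       14.046
```

The APECED archetype's low Dirichlet concentration yields expanded
repertoires — higher Gini (less diversity, a few dominant clones) and lower
R20 than HC — while the broad-but-unexpanded SLE archetype sits below the
HC median; autoimmune groups carry the planted lower mutation load.

The full pipeline runs from one config:

```bash
autorep run --config configs/demo.yaml --outdir demo_out
autorep report --outdir demo_out
```

writing normalized intensities, the Z matrix with its baseline audit table,
reactivity/overlap/hot-cold/volcano/PCA tables, localization breakdowns,
IFN scores, repertoire summaries and a JSON manifest with SHA-256 digests
(byte-identical across reruns of the same config and seed). Individual
stages are also available as subcommands (`simulate`, `normalize`,
`zscore`, `reactivity`, `localization`, `expression`, `bcr`).

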