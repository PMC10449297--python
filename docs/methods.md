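# Methods

## Scope and data model

The pipeline operates on dense genes × cells FPKM matrices with per-cell
metadata (patient, compartment ∈ {BMMC, CPC}, mapped reads, detected
genes). FPKM is stored untransformed; every stage that needs a log scale
computes log2(FPKM + 1) on the fly. Gene identifiers are opaque symbols
from a single annotation — no identifier mapping is attempted. Read
alignment and FPKM quantification are upstream of this package.

## Filtering

Cells are kept when mapped reads > 1e5 **and** detected genes > 1e3, both
strict inequalities. `n_genes_detected` is taken from the metadata when
present (upstream pipelines define their own count) and recomputed as
#(FPKM > 0) only when missing. A transcript is stably expressed when its
FPKM exceeds 1 in at least one cell (strict). Both filters are idempotent
and monotone in their thresholds; an empty result is a warning, not an
error.

## Immunoglobulin specificity

Ig genes are recognized by symbol prefix (IGH/IGK/IGL, case-insensitive).
Each Ig gene is tested with a classical one-way ANOVA of its FPKM values
grouped by patient — raw FPKM by default, matching the scale on which the
values are reported, with a log2(FPKM+1) toggle. Patients with fewer than
two cells are excluded with a warning; dropout zeros are ordinary
observations; an all-constant gene is defined to have F = 0, p = 1. A gene
is patient-specific at p < 1e-6 (no multiple-testing correction — the
cutoff is already extreme and the gene family small).

Which patient a significant gene belongs to has no canonical definition;
we use a leave-one-out outlier rule: patient p is listed when its group
mean exceeds mean + 2·sd of the *other* patients' means (with two
patients, the larger mean). The leave-one-out form matters: with few
patients, a single strongly expressing group inflates any threshold built
from *all* group means (grand mean + 2·sd can exceed the top group's own
mean once k ≤ 4), whereas excluding the candidate keeps the rule usable at
any patient count and still allows a gene to be specific to several
patients, which does occur.

## Differential expression

Per-gene tests are two-sided unpaired Welch t-tests on FPKM (the unequal-
variance form is the robust default for "unpaired t test"; a pooled toggle
is not offered because scipy exposes both through one call). Fold change
is log2((mean_A + 1)/(mean_B + 1)) — ratio of group means with pseudocount
1, stable under dropout zeros; group A is the CPCs (or first cluster).
The DEG call is conjunctive: p < 0.05 and |log2FC| > 1 must hold in every
required patient contrast; contrasts with under two cells per group are
dropped with a warning. Raw p-values drive the call (no correction), with
Benjamini–Hochberg q-values reported alongside for transparency. A
per-patient p-cutoff override supports stricter within-patient cluster
contrasts.

The whole-transcriptome level comparison summarizes each gene by its mean
log2(FPKM+1) within each cell group and compares the two per-gene vectors:
Kolmogorov–Smirnov for compartment comparisons, Mann–Whitney for cluster
comparisons, Welch t for population-style comparisons; the sign of the
median difference gives the direction. A per-cell aggregate (each cell's
mean over the gene set) is available behind a flag. Note the per-gene
vectors share each gene's baseline, which rank and KS tests on marginals
cannot exploit; their power therefore grows with the number of genes, and
the comparison is meant for transcriptome-scale gene sets.

## Clustering and FAM46C grouping

Features are the conjunctive DEG set united with the detected Ig genes
(log2(FPKM+1), per-gene z-score; zero-variance genes dropped). When no DEG
contrast exists the top-500-variance expressed genes substitute, loudly
logged. The clustering algorithm is agglomerative with Ward linkage on
Euclidean distance — chosen for determinism (no random initialization);
k-means would require seeding policy for the same result. Cluster indices
are canonicalized by decreasing size (ties by smallest member id), making
partitions invariant to input order. k is scanned over [1, 10] ∩
[2, n−1]; k = 1 has no defined silhouette and scores 0 by convention, so
any real structure wins; ties go to the smaller k. The 2-D PCA embedding
is cosmetic and untested.

The FAM46C grouping anchors "high" at the cluster with the largest mean
FAM46C log2(FPKM+1) and merges all remaining clusters into "low". The
low-vs-high Welch p-value is reported but never changes the labels — a
non-significant split keeps its grouping, mirroring how borderline
patients are still labeled.

## Metastasis model

Pearson correlations are computed between every CPC and BMMC of a patient
over the expressed-gene set on log2(FPKM+1) — the log scale prevents a few
very-high-FPKM genes from dominating r (raw-scale toggle available). Each
CPC takes the argmax-r BMMC; ties break to the lexicographically smallest
BMMC id and are flagged; zero-variance cells yield NaN correlations and
are excluded (an all-NaN CPC is dropped from C_p). With C_j CPCs assigned
to BMMC j and C_p analyzed in total, M_j = C_j/C_p; conservation
(Σ C_j = C_p, Σ M_j = 1) holds by construction and is asserted in tests.
Contributions aggregate by FAM46C group as fractions, presented as
percentages at one decimal. The low-vs-high rate comparison is a
two-sided Mann–Whitney test over per-BMMC rates, including zero-rate
BMMCs. No correlation floor is applied: every CPC gets a contributor, as
the model prescribes.

## Synthetic data

The generator plants, on the log2(FPKM+1) scale: per-gene baselines
N(3, 1.5²); per-cell noise N(0, 0.4²); Ig genes silent at −2 except the
patient's specific genes (+4) and per-subclone marker genes (+5 within one
cluster); FAM46C-low clusters get a −2 FAM46C shift and a ×0.7 global
FPKM scale (the mRNA-stability depression); CPCs copy their source BMMC's
log2 profile plus N(0, noise_sd = 0.3), a −3.53 FAM46C shift and ±1.5
shifts on 40 planted DEG genes; FPKM = max(0, 2^x − 1); entries under
FPKM 5 drop out with probability 0.1. Scenario geometries: P17-like —
clusters (20, 14, 12), low {0, 2}, 30 CPCs sourced (13, 5, 12), so 25/30
low-cluster sources; P20-like — clusters (24, 20), low {1}, 47 CPCs
sourced (12, 35). The P20 split is a free choice within the constraint
that the low cluster dominates; per-cluster BMMC counts are likewise free
parameters chosen at realistic Smart-seq2 plate scale.

Three generator choices deserve emphasis. (a) Subclone Ig markers exist
because two FAM46C-low clusters would otherwise be distributionally
identical and no algorithm could tell them apart; differential Ig
expression between subclones is exactly the heterogeneity the analysis
targets, and Ig genes are part of the clustering feature space. Markers
are allocated round-robin over the low clusters (the high cluster is
already set apart by FAM46C and the global scale) and only when a
scenario has ≥ 2 clusters. (b) The FAM46C baseline is pinned at log2 = 4
rather than drawn: a draw leaves the pivot gene below the expression
cutoff in ~9% of realizations, where the analysis is undefined. (c)
Planted-DEG baselines are floored at log2 = 2: FPKM floors at zero, so a
−1.5 shift on a gene with mean FPKM < 1 carries no recoverable
|log2FC| > 1 — an unexpressible "effect" is not a planted effect.

What the generator does *not* emulate: count noise, gene–gene correlation,
batch effects, doublets, library-size variation, UMI structure. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct when its structural assumptions hold, not that those assumptions
hold in any particular real data set.

## Numerical choices and degenerate inputs

Welch tests with zero variance in both groups and equal means give p = 1;
ANOVA on constant data gives F = 0, p = 1; KS/Mann–Whitney on identical
vectors give p = 1 (≥ 0.99 under tie handling). Round-trips through TSV
preserve values to 1e-9 relative (10 significant digits written). Oracle
tolerances in the test suite: 1e-10 for ANOVA/Welch/silhouette against
closed-form or O(n²) recomputation, 1e-12 for Pearson, exact for argmax
assignment including the tie rule. Identical seeds give bit-identical
matrices on one platform.

## Problem sizes

Tests and the acceptance script run the pipeline at the scenarios' native
scale (2 000 genes, 46–76 cells per patient) over 25–100 seeded
realizations per property — a single pipeline run takes well under a
second, so whole recovery suites complete in seconds.

## Known limitations

FPKM-level t-tests ignore count uncertainty (no negative-binomial or
pseudobulk model); the best-match assignment is hard (no probabilistic
source attribution); clustering is feature-dependent and inherits any DEG
miscalls; the specificity attribution rule is a pragmatic outlier
heuristic, not an inferential procedure; survival/population-cohort
analyses on external datasets are out of scope.
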