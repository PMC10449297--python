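# fam46c-hetero

A single-cell RNA-seq (Smart-seq2, FPKM) analysis pipeline for studying
FAM46C-mediated tumor heterogeneity in multiple myeloma (MM) and its role in
extramedullary metastasis.

In MM, malignant plasma cells reside in the bone marrow (BMMCs) and a small
clonal population circulates in peripheral blood (clonal circulating plasma
cells, CPCs) — the cells that seed extramedullary disease. FAM46C is a
non-canonical poly(A) polymerase and MM tumor suppressor whose loss reduces
mRNA stability, depressing the whole transcriptome. This package implements
the analysis chain that connects those observations at single-cell
resolution:

1. **QC** — keep cells with > 1e5 mapped reads and > 1e3 detected genes;
   keep transcripts with FPKM > 1 in at least one cell.
2. **Immunoglobulin specificity** — one-way ANOVA of each Ig gene's FPKM
   across patients; p < 1e-6 marks a gene as patient-specifically expressed
   (the clonotypic signature that verifies sample identity).
3. **Differential expression** — two-sided unpaired Welch t-test of CPCs vs
   BMMCs per patient; a gene is a DEG only if p < 0.05 **and**
   |log2 FC| > 1 hold *conjunctively* in every required patient. Whole-
   transcriptome level shifts are tested on per-gene group means
   (Kolmogorov–Smirnov / Mann–Whitney / Welch t).
4. **Clustering** — Ward-linkage agglomerative clustering of BMMCs on the
   z-scored log2(FPKM+1) DEG ∪ Ig feature space; the cluster number k ∈
   [1, 10] is chosen by the largest average silhouette width
   s(i) = (b(i) − a(i)) / max(a(i), b(i)). The cluster with the highest mean
   FAM46C is the *high* group; all others merge into the *low* group.
5. **Metastasis model** — each CPC is matched to the BMMC with the largest
   Pearson correlation of log2(FPKM+1) profiles ("possible contributor").
   With C_p CPCs analyzed and C_j assigned to BMMC j, the per-cell
   metastasis rate is **M_j = C_j / C_p** (Σ M_j = 1); rates aggregate into
   per-cluster contribution fractions and export as a three-layer Sankey
   graph (cluster → BMMC → CPC).

Because no raw patient matrices are publicly deposited, the package ships a
first-class synthetic-data module (`fam46c_hetero.synthetic_data`) that
generates FPKM matrices with the planted structure the analysis assumes —
patient-specific Ig genes, FAM46C-low/high BMMC subclusters with a globally
depressed transcriptome, CPCs copied from designated BMMC source cells with
noise and dropout — so every stage runs and is testable offline.

## Worked example

Simulate the P17-like scenario (3 BMMC subclusters, two of them FAM46C-low,
30 CPCs of which 25 originate in the low clusters) and run the pipeline:

```sh
fam46c-hetero simulate --scenario p17 --seed 7 --out sim17/
fam46c-hetero run --matrix sim17/matrix.tsv --meta sim17/meta.tsv --out run17/
```

prints

```
wrote 2000 genes x 76 cells to sim17
P17: k=3, C_p=30, contribution%={'high': 16.7, 'low': 83.3}
outputs: 8 files under run17/
```

Reading: the silhouette scan selected k = 3 BMMC clusters (the planted
number); all 30 CPCs were assigned a best-correlated BMMC contributor; the
merged FAM46C-low group contributed 83.3% of the CPCs (25/30) and the high
group 16.7% — low-FAM46C subclones dominate the metastatic outflow. Per-cell
rates (`rates.tsv`), the contribution split (`contributions.json`), the
Sankey graph (`sankey.json`), cluster labels, the silhouette scan and the
DEG table are written under `run17/` with a manifest.

The same analysis is available as a library:

```python
from fam46c_hetero import generate_patient, scenario_p17
from fam46c_hetero.pipeline import run_patient

matrix, truth = generate_patient(scenario_p17(seed=7))
res = run_patient(matrix, "P17")
res.metastasis.cluster_contribution   # {'high': 0.1667, 'low': 0.8333}
```

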