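"""Unsupervised BMMC clustering with silhouette-selected cluster number.

Cells are clustered on the differential-expression ∪ immunoglobulin gene
space after log2(FPKM+1) transform and per-gene z-scoring.  The algorithm
is agglomerative clustering with Ward linkage on Euclidean distance — a
deterministic choice with no random initialization — cut at each candidate
k from the configured range.  The average silhouette width

    s(i) = (b(i) - a(i)) / max(a(i), b(i))

is computed for every k ≥ 2 (k = 1 is assigned width 0 by convention) and
the k with the largest average width is selected, ties going to the
smaller k.

Clusters are then labeled FAM46C-low/-high: the cluster with the highest
mean FAM46C (log scale) anchors the high group and every other cluster is
merged into the low group; the low-vs-high difference is quantified with a
two-sided Welch t-test on FAM46C but does not alter the labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io_model import ExpressionMatrix

__all__ = [
    "ClusterModel",
    "Fam46cGrouping",
    "feature_matrix",
    "cluster_cells",
    "select_k_silhouette",
    "label_fam46c_groups",
]


@dataclass(frozen=True)
class ClusterModel:
    k_selected: int
    labels: dict[str, int]  # cell id -> cluster index in 1..k
    avg_silhouette_by_k: dict[int, float]
    feature_genes: tuple[str, ...]
    embedding: dict[str, tuple[float, float]] = field(default_factory=dict)

    def labels_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": list(self.labels), "cluster": list(self.labels.values())}
        )

    def silhouette_table(self) -> pd.DataFrame:
        ks = sorted(self.avg_silhouette_by_k)
        return pd.DataFrame(
            {"k": ks, "avg_silhouette": [self.avg_silhouette_by_k[k] for k in ks]}
        )


@dataclass(frozen=True)
class Fam46cGrouping:
    group_of_cluster: dict[int, str]  # cluster index -> "low" | "high"
    fam46c_mean_by_cluster: dict[int, float]
    p_value_low_vs_high: float
    merged_low: tuple[int, ...]
    merged_high: tuple[int, ...]


def feature_matrix(
    m: ExpressionMatrix, feature_genes: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Cells x features matrix: log2(FPKM+1) then per-gene z-score.

    Zero-variance genes are dropped with a warning; returns the matrix and
    the retained gene list.  Raises when nothing survives.
    """
    present = [g for g in feature_genes if g in set(m.gene_ids)]
    if not present:
        raise ValueError("no feature genes present in the matrix")
    logv = m.subset_genes(present).log2p1()  # genes x cells
    sd = logv.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(present, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)", stacklevel=2)
    if not keep.any():
        raise ValueError("all feature genes have zero variance")
    logv = logv[keep]
    kept = [g for g, k in zip(present, keep) if k]
    z = (logv - logv.mean(axis=1, keepdims=True)) / logv.std(axis=1, keepdims=True)
    return z.T, kept  # cells x features


def _canonical_labels(raw: np.ndarray, cell_ids: list[str]) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size, ties by smallest member id."""
    order = []
    for lab in np.unique(raw):
        members = [cell_ids[i] for i in np.flatnonzero(raw == lab)]
        order.append((-len(members), min(members), lab))
    mapping = {lab: new + 1 for new, (_, _, lab) in enumerate(sorted(order))}
    return np.array([mapping[l] for l in raw])


def cluster_cells(features: np.ndarray, k: int, cell_ids: list[str]) -> dict[str, int]:
    """Ward-linkage agglomerative clustering cut at k clusters.

    Deterministic for fixed input; cluster indices run 1..k ordered by
    decreasing cluster size (ties by smallest member cell id).
    """
    n = features.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} cells")
    if k == 1:
        raw = np.zeros(n, dtype=int)
    else:
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(features)
    labels = _canonical_labels(raw, cell_ids)
    return {c: int(l) for c, l in zip(cell_ids, labels)}


def select_k_silhouette(
    features: np.ndarray,
    cell_ids: list[str],
    k_range: tuple[int, int] = (1, 10),
    feature_genes: tuple[str, ...] = (),
) -> ClusterModel:
    """Scan k over ``k_range``, score by average silhouette width, pick argmax.

    Only 2 <= k <= n_cells - 1 admit a silhouette; k = 1 scores 0 by
    convention.  Ties are broken toward the smaller k.  The returned model
    carries labels at the selected k and a 2-D PCA embedding for plotting.
    """
    n = features.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to select a cluster number")
    lo, hi = k_range
    widths: dict[int, float] = {}
    labelings: dict[int, dict[str, int]] = {}
    for k in range(lo, hi + 1):
        if k == 1:
            widths[1] = 0.0
            labelings[1] = cluster_cells(features, 1, cell_ids)
            continue
        if k > n - 1:
            break
        labs = cluster_cells(features, k, cell_ids)
        arr = np.array([labs[c] for c in cell_ids])
        widths[k] = float(silhouette_score(features, arr, metric="euclidean"))
        labelings[k] = labs
    if not widths:
        raise ValueError("k_range contains no evaluable k")
    k_best = max(sorted(widths), key=lambda k: (widths[k], -k))
    n_comp = min(2, n, features.shape[1])
    coords = PCA(n_components=n_comp).fit_transform(features)
    if n_comp < 2:
        coords = np.column_stack([coords, np.zeros(n)])
    return ClusterModel(
        k_selected=k_best,
        labels=labelings[k_best],
        avg_silhouette_by_k=widths,
        feature_genes=tuple(feature_genes),
        embedding={c: (float(x), float(y)) for c, (x, y) in zip(cell_ids, coords)},
    )


def label_fam46c_groups(
    m: ExpressionMatrix,
    labels: dict[str, int],
    fam46c_gene: str = "FAM46C",
) -> Fam46cGrouping:
    """Split clusters into a FAM46C-high anchor and a merged low group.

    The cluster with the highest mean FAM46C log2(FPKM+1) is "high"; all
    other clusters are merged as "low".  The reported t-test p-value
    quantifies the low-vs-high FAM46C difference but never changes the
    labels (non-significant splits keep their grouping).
    """
    if fam46c_gene not in set(m.gene_ids):
        raise KeyError(f"{fam46c_gene} not present in matrix")
    logf = np.log2(m.gene_row(fam46c_gene) + 1.0)
    by_cell = dict(zip(m.cell_ids, logf))
    clusters = sorted(set(labels.values()))
    means = {
        t: float(np.mean([by_cell[c] for c, l in labels.items() if l == t]))
        for t in clusters
    }
    high = max(sorted(means), key=lambda t: means[t])
    low = tuple(t for t in clusters if t != high)
    lo_vals = np.array([by_cell[c] for c, l in labels.items() if l != high])
    hi_vals = np.array([by_cell[c] for c, l in labels.items() if l == high])
    if len(lo_vals) >= 2 and len(hi_vals) >= 2:
        _, p = stats.ttest_ind(lo_vals, hi_vals, equal_var=False)
        p = float(p) if np.isfinite(p) else 1.0
    else:
        p = float("nan")
    return Fam46cGrouping(
        group_of_cluster={t: ("high" if t == high else "low") for t in clusters},
        fam46c_mean_by_cluster=means,
        p_value_low_vs_high=p,
        merged_low=low,
        merged_high=(high,),
    )
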