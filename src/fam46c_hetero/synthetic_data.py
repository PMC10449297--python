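"""Synthetic Smart-seq2-style FPKM matrices with planted structure.

The generator emulates the statistical shape of the study data rather than
its distributional detail: a log-normal per-gene baseline, patient-specific
immunoglobulin genes, bone-marrow (BMMC) subclusters that differ in FAM46C
and in overall transcriptome level, and circulating plasma cells (CPCs)
that are noisy copies of designated BMMC source cells.  Every planted fact
(cluster membership, CPC source cell, specific Ig genes, shifted genes) is
returned as :class:`GroundTruth` so downstream stages can be scored against
it.

Generative model, on the log2(FPKM+1) scale unless noted:

1. per-gene baseline ``b_g ~ Normal(3, 1.5)``;
2. BMMC cell value ``x_gc = b_g + Normal(0, 0.4)``;
3. cells of FAM46C-low clusters: FAM46C gets ``fam46c_low_log2_shift``
   added, and their final FPKM are multiplied by ``global_low_scale``
   (the transcriptome-wide depression that accompanies low FAM46C);
4. immunoglobulin genes sit at baseline -2 (effectively silent) except the
   patient's own specific genes (+4) and per-subclone marker genes
   (+``cluster_ig_log2_shift`` within one cluster) — subclones of one
   tumor differ in which Ig variable segments they transcribe;
5. each CPC copies its source BMMC's log2 values, adds per-gene
   ``Normal(0, noise_sd)``, shifts FAM46C by ``cpc_fam46c_log2_shift`` and
   the planted DEG genes by ±``deg_log2_shift`` (half up, half down);
6. ``FPKM = max(0, 2**x - 1)``;
7. dropout: entries with FPKM < 5 are zeroed with probability
   ``dropout_rate``;
8. metadata: mapped reads ~ Uniform[2e5, 2e6]; detected genes counted from
   the final matrix (FPKM > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, concat_cells

__all__ = [
    "IG_GENE_POOL",
    "ScenarioConfig",
    "GroundTruth",
    "gene_symbols",
    "generate_patient",
    "generate_cohort",
    "scenario_p17",
    "scenario_p20",
]

FAM46C = "FAM46C"

# Twelve immunoglobulin symbols spanning the IGH/IGK/IGL loci; matches the
# default n_ig_genes so symbol sets are stable across patients of a cohort.
IG_GENE_POOL = (
    "IGKV1-33",
    "IGHV4-28",
    "IGKV3D-7",
    "IGHA1",
    "IGHV1-24",
    "IGHV3-43",
    "IGKV3D-20",
    "IGKV4-1",
    "IGKC",
    "IGLV3-19",
    "IGLL5",
    "IGLV3-1",
)

#: FPKM below this value is eligible for dropout (technical zeros hit
#: low-expression entries preferentially).
DROPOUT_FPKM_CEILING = 5.0

BASELINE_MEAN = 3.0
BASELINE_SD = 1.5
CELL_NOISE_SD = 0.4
IG_BASELINE = -2.0
IG_SPECIFIC_SHIFT = 4.0
#: FAM46C baseline is pinned (not drawn) so the gene the analysis pivots on
#: is reliably expressed in every realization.
FAM46C_BASELINE = 4.0
#: Planted-DEG baselines are floored here (log2 scale).  FPKM cannot go
#: below zero, so a downward shift planted on a near-silent gene carries no
#: recoverable fold change; a planted effect must sit on a stably expressed
#: gene to be an effect at all.
DEG_BASELINE_FLOOR = 2.0


class ConfigError(ValueError):
    """A scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one patient's matrix.

    ``cluster_sizes`` gives the BMMC count of each planted subcluster and
    ``low_clusters`` designates which of them are FAM46C-low.
    ``cpc_source_counts[t]`` is the number of CPCs whose source BMMC lies in
    cluster ``t`` (summing to ``n_cpc``).  ``specific_ig`` indexes into the
    immunoglobulin pool and names this patient's clone-defining Ig genes.
    """

    patient_id: str
    cluster_sizes: tuple[int, ...]
    n_cpc: int
    cpc_source_counts: tuple[int, ...]
    low_clusters: frozenset[int] = frozenset()
    n_genes: int = 2000
    n_ig_genes: int = 12
    fam46c_low_log2_shift: float = -2.0
    global_low_scale: float = 0.7
    cpc_fam46c_log2_shift: float = -3.53
    noise_sd: float = 0.3
    dropout_rate: float = 0.1
    seed: int = 0
    specific_ig: tuple[int, ...] = (0, 1)
    cluster_ig_log2_shift: float = 5.0
    n_deg_genes: int = 40
    deg_log2_shift: float = 1.5

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) < 2:
            raise ConfigError("need at least 2 BMMC cells in total")
        if len(self.cpc_source_counts) != len(self.cluster_sizes):
            raise ConfigError("cpc_source_counts must align with cluster_sizes")
        if sum(self.cpc_source_counts) != self.n_cpc:
            raise ConfigError("cpc_source_counts must sum to n_cpc")
        if any(n < 0 for n in self.cpc_source_counts):
            raise ConfigError("negative cpc_source_counts")
        for t, n in enumerate(self.cpc_source_counts):
            if n > 0 and self.cluster_sizes[t] == 0:
                raise ConfigError(f"cpc_source_counts references empty cluster {t}")
        if not 0 < self.global_low_scale <= 1:
            raise ConfigError("global_low_scale must be in (0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if any(t < 0 or t >= len(self.cluster_sizes) for t in self.low_clusters):
            raise ConfigError("low_clusters index out of range")
        if any(i < 0 or i >= self.n_ig_genes for i in self.specific_ig):
            raise ConfigError("specific_ig index out of range")
        if self.n_ig_genes > len(IG_GENE_POOL):
            raise ConfigError(f"at most {len(IG_GENE_POOL)} Ig genes available")
        if self.n_genes < 1 + self.n_ig_genes + self.n_deg_genes:
            raise ConfigError("n_genes too small for FAM46C + Ig + DEG genes")


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels of one generated patient, for recovery scoring."""

    bmmc_cluster_of_cell: Mapping[str, int]
    source_bmmc_of_cpc: Mapping[str, str]
    ig_gene_of_patient: Mapping[str, tuple[str, ...]]
    planted_deg_genes: tuple[str, ...]
    cluster_marker_ig: Mapping[int, tuple[str, ...]] = field(default_factory=dict)


def gene_symbols(cfg: ScenarioConfig) -> list[str]:
    """Deterministic gene list: FAM46C, the Ig pool, then numbered fillers.

    Depends only on ``n_genes``/``n_ig_genes`` so that patients generated
    with equal dimensions share one symbol space and can form a cohort.
    """
    n_filler = cfg.n_genes - 1 - cfg.n_ig_genes
    fillers = [f"GEN{i:04d}" for i in range(n_filler)]
    return [FAM46C, *IG_GENE_POOL[: cfg.n_ig_genes], *fillers]


def planted_deg_symbols(cfg: ScenarioConfig) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(up-shifted, down-shifted) planted DEG symbols; fixed across patients.

    The last ``n_deg_genes`` filler genes are used so two patients of a
    cohort plant the *same* genes, as the conjunctive cross-patient DEG rule
    requires.
    """
    symbols = gene_symbols(cfg)
    degs = symbols[len(symbols) - cfg.n_deg_genes :] if cfg.n_deg_genes else []
    half = len(degs) // 2
    return tuple(degs[:half]), tuple(degs[half:])


def _cluster_marker_assignment(cfg: ScenarioConfig) -> dict[int, list[int]]:
    """Round-robin Ig-pool indices (minus the patient's own) to clusters.

    Markers make subclones of one tumor distinguishable in the Ig dimension,
    mirroring the observed differential Ig expression between clusters.
    FAM46C-low clusters are served first: the high cluster is already set
    apart by FAM46C itself and the global transcriptome depression, whereas
    two low clusters would otherwise be statistically identical.
    """
    k = len(cfg.cluster_sizes)
    if k < 2:
        return {}
    available = [i for i in range(cfg.n_ig_genes) if i not in cfg.specific_ig]
    low = sorted(cfg.low_clusters)
    order = low + [t for t in range(k) if t not in cfg.low_clusters]
    targets = low if len(low) >= 2 else order
    assignment: dict[int, list[int]] = {t: [] for t in range(k)}
    for j, ig_idx in enumerate(available):
        assignment[targets[j % len(targets)]].append(ig_idx)
    return assignment


def generate_patient(cfg: ScenarioConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one patient's BMMC + CPC FPKM matrix and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    symbols = gene_symbols(cfg)
    n_genes = len(symbols)
    n_bmmc = sum(cfg.cluster_sizes)
    fam_idx = symbols.index(FAM46C)
    ig_idx = {name: symbols.index(name) for name in IG_GENE_POOL[: cfg.n_ig_genes]}

    # (1) per-gene baseline; Ig genes pinned near silence
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    baseline[fam_idx] = FAM46C_BASELINE
    up, down = planted_deg_symbols(cfg)
    for name in up + down:
        i = symbols.index(name)
        baseline[i] = max(baseline[i], DEG_BASELINE_FLOOR)
    for i in ig_idx.values():
        baseline[i] = IG_BASELINE
    specific_syms = tuple(IG_GENE_POOL[i] for i in cfg.specific_ig)
    for name in specific_syms:
        baseline[ig_idx[name]] += IG_SPECIFIC_SHIFT

    # (2) BMMC log2 values
    x = baseline[:, None] + rng.normal(0.0, CELL_NOISE_SD, size=(n_genes, n_bmmc))

    cluster_of = np.repeat(np.arange(len(cfg.cluster_sizes)), cfg.cluster_sizes)
    low_mask = np.isin(cluster_of, sorted(cfg.low_clusters))

    # (3) FAM46C shift in low clusters (global scale applied on FPKM below)
    x[fam_idx, low_mask] += cfg.fam46c_low_log2_shift

    # (4) per-cluster Ig marker genes
    markers = _cluster_marker_assignment(cfg)
    marker_syms: dict[int, tuple[str, ...]] = {}
    for t, idxs in markers.items():
        marker_syms[t] = tuple(IG_GENE_POOL[i] for i in idxs)
        cells_t = cluster_of == t
        for i in idxs:
            x[ig_idx[IG_GENE_POOL[i]], cells_t] += cfg.cluster_ig_log2_shift

    # (5) CPCs copy their source BMMC with noise and planted shifts
    sources: list[int] = []
    for t, count in enumerate(cfg.cpc_source_counts):
        members = np.flatnonzero(cluster_of == t)
        sources.extend(rng.choice(members, size=count, replace=True))
    sources = list(map(int, sources))
    y = x[:, sources] + rng.normal(0.0, cfg.noise_sd, size=(n_genes, cfg.n_cpc))
    y[fam_idx, :] += cfg.cpc_fam46c_log2_shift
    for name in up:
        y[symbols.index(name), :] += cfg.deg_log2_shift
    for name in down:
        y[symbols.index(name), :] -= cfg.deg_log2_shift

    # (6) to FPKM; low-cluster BMMCs get the global transcriptome depression
    fpkm_b = np.maximum(0.0, np.exp2(x) - 1.0)
    fpkm_b[:, low_mask] *= cfg.global_low_scale
    fpkm_c = np.maximum(0.0, np.exp2(y) - 1.0)
    fpkm = np.hstack([fpkm_b, fpkm_c])

    # (7) dropout on low-expression entries
    if cfg.dropout_rate > 0:
        drop = (fpkm < DROPOUT_FPKM_CEILING) & (
            rng.random(fpkm.shape) < cfg.dropout_rate
        )
        fpkm[drop] = 0.0

    # (8) cell metadata
    bmmc_ids = [f"{cfg.patient_id}-B{i:03d}" for i in range(n_bmmc)]
    cpc_ids = [f"{cfg.patient_id}-C{i:03d}" for i in range(cfg.n_cpc)]
    cell_ids = bmmc_ids + cpc_ids
    meta = pd.DataFrame(
        {
            "patient_id": cfg.patient_id,
            "compartment": ["BMMC"] * n_bmmc + ["CPC"] * cfg.n_cpc,
            "mapped_reads": rng.integers(int(2e5), int(2e6), size=len(cell_ids)),
            "n_genes_detected": (fpkm > 0).sum(axis=0),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(symbols, cell_ids, fpkm, meta)
    truth = GroundTruth(
        bmmc_cluster_of_cell={c: int(t) for c, t in zip(bmmc_ids, cluster_of)},
        source_bmmc_of_cpc={c: bmmc_ids[s] for c, s in zip(cpc_ids, sources)},
        ig_gene_of_patient={cfg.patient_id: specific_syms},
        planted_deg_genes=up + down,
        cluster_marker_ig=marker_syms,
    )
    return matrix, truth


def generate_cohort(
    configs: Sequence[ScenarioConfig],
) -> tuple[ExpressionMatrix, dict[str, GroundTruth]]:
    """Generate several patients sharing one gene space and stack their cells."""
    matrices, truths = [], {}
    for cfg in configs:
        m, t = generate_patient(cfg)
        matrices.append(m)
        truths[cfg.patient_id] = t
    return concat_cells(matrices), truths


def scenario_p17(seed: int = 0, **overrides) -> ScenarioConfig:
    """P17-like geometry: 3 BMMC clusters (two FAM46C-low) and 30 CPCs.

    25 of the 30 CPC source cells lie in the low clusters, so exact recovery
    yields a 25/30 = 83.3% low-group contribution.
    """
    params = dict(
        patient_id="P17",
        cluster_sizes=(20, 14, 12),
        low_clusters=frozenset({0, 2}),
        n_cpc=30,
        cpc_source_counts=(13, 5, 12),
        specific_ig=(0, 1),
        seed=seed,
    )
    params.update(overrides)
    return ScenarioConfig(**params)


def scenario_p20(seed: int = 0, **overrides) -> ScenarioConfig:
    """P20-like geometry: 2 BMMC clusters (one FAM46C-low) and 47 CPCs.

    The low cluster supplies the majority of CPC sources (35 of 47); the
    exact split is a free choice of the scenario.
    """
    params = dict(
        patient_id="P20",
        cluster_sizes=(24, 20),
        low_clusters=frozenset({1}),
        n_cpc=47,
        cpc_source_counts=(12, 35),
        specific_ig=(2, 3),
        seed=seed,
    )
    params.update(overrides)
    return ScenarioConfig(**params)
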