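"""The extramedullary-metastasis contribution model.

Every clonal circulating plasma cell (CPC) is matched to the bone-marrow
cell (BMMC) it correlates best with: Pearson correlation of log2(FPKM+1)
profiles over a shared gene set, argmax per CPC, ties broken toward the
lexicographically smallest BMMC id.  The matched BMMC is the CPC's
"possible contributor"; a BMMC can contribute 0, 1 or many CPCs.

With C_p CPCs analyzed and C_j of them assigned to BMMC j, the per-cell
metastasis rate is

    M_j = C_j / C_p,

so the rates sum to one.  Rates aggregate to per-cluster (and FAM46C
low/high group) contribution fractions, the low-vs-high rate difference is
tested with a two-sided Mann-Whitney test over per-BMMC rates, and the
whole cluster → BMMC → CPC flow exports as a three-layer Sankey node-link
graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Fam46cGrouping
from .diffexpr import ShiftTestResult
from .io_model import ExpressionMatrix

__all__ = [
    "MetastasisReport",
    "correlation_matrix",
    "assign_best_match",
    "metastasis_rates",
    "cluster_contributions",
    "compare_rates_by_group",
    "export_sankey",
    "build_report",
]


@dataclass(frozen=True)
class MetastasisReport:
    assignments: dict[str, tuple[str, float]]  # CPC id -> (BMMC id, r)
    c_j: dict[str, int]
    c_p: int
    m_j: dict[str, float]
    cluster_contribution: dict[str, float]
    rate_comparison: ShiftTestResult | None
    sankey: dict = field(default_factory=dict)
    tie_cpcs: tuple[str, ...] = ()
    cluster_of_bmmc: dict[str, int] = field(default_factory=dict)
    group_of_bmmc: dict[str, str] = field(default_factory=dict)

    def rates_table(self) -> pd.DataFrame:
        rows = [
            {
                "bmmc_id": j,
                "cluster": self.cluster_of_bmmc.get(j),
                "group": self.group_of_bmmc.get(j),
                "C_j": self.c_j[j],
                "M_j": self.m_j[j],
            }
            for j in self.c_j
        ]
        return pd.DataFrame(rows)


def correlation_matrix(
    cpc: ExpressionMatrix,
    bmmc: ExpressionMatrix,
    genes: Sequence[str],
    scale: str = "log",
) -> pd.DataFrame:
    """Pearson r between every CPC and every BMMC over a shared gene set.

    Profiles are log2(FPKM+1) by default (``scale="raw"`` uses FPKM
    directly).  A cell with zero variance over the gene set yields NaN
    correlations and is excluded from downstream argmax with a warning.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes")
    a = cpc.subset_genes(genes)
    b = bmmc.subset_genes(genes)
    xa = a.log2p1() if scale == "log" else a.values
    xb = b.log2p1() if scale == "log" else b.values
    za = xa - xa.mean(axis=0, keepdims=True)
    zb = xb - xb.mean(axis=0, keepdims=True)
    sa = np.sqrt((za**2).sum(axis=0))
    sb = np.sqrt((zb**2).sum(axis=0))
    dead_a = sa == 0
    dead_b = sb == 0
    if dead_a.any() or dead_b.any():
        warnings.warn("cell(s) with zero variance over the gene set", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (za.T @ zb) / np.outer(sa, sb)
    r[dead_a, :] = np.nan
    r[:, dead_b] = np.nan
    return pd.DataFrame(r, index=a.cell_ids, columns=b.cell_ids)


def assign_best_match(
    corr: pd.DataFrame,
) -> tuple[dict[str, tuple[str, float]], tuple[str, ...]]:
    """Argmax-r BMMC per CPC; ties to the smallest BMMC id.

    Returns (assignments, tied_cpc_ids).  CPCs whose correlations are all
    NaN are dropped with a warning (they do not count toward C_p).
    """
    assignments: dict[str, tuple[str, float]] = {}
    ties: list[str] = []
    bmmc_ids = np.asarray(corr.columns)
    for cpc_id, row in zip(corr.index, corr.to_numpy()):
        finite = np.isfinite(row)
        if not finite.any():
            warnings.warn(f"CPC {cpc_id} has no finite correlation; dropped", stacklevel=2)
            continue
        best = np.nanmax(row)
        winners = sorted(bmmc_ids[finite & (row == best)])
        if len(winners) > 1:
            ties.append(cpc_id)
        assignments[cpc_id] = (winners[0], float(best))
    return assignments, tuple(ties)


def metastasis_rates(
    assignments: Mapping[str, tuple[str, float]],
    bmmc_ids: Sequence[str],
    c_p: int | None = None,
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-BMMC counts C_j and rates M_j = C_j / C_p (0 for unmatched BMMCs)."""
    if c_p is None:
        c_p = len(assignments)
    if c_p <= 0:
        raise ValueError("C_p must be positive")
    c_j = {j: 0 for j in bmmc_ids}
    for bmmc_id, _ in assignments.values():
        c_j[bmmc_id] += 1
    m_j = {j: n / c_p for j, n in c_j.items()}
    return c_j, m_j


def cluster_contributions(
    assignments: Mapping[str, tuple[str, float]],
    group_of_bmmc: Mapping[str, str],
) -> dict[str, float]:
    """Fraction of CPCs whose contributor lies in each group (sums to 1)."""
    c_p = len(assignments)
    if c_p == 0:
        raise ValueError("no assignments")
    counts: dict[str, int] = {}
    for bmmc_id, _ in assignments.values():
        if bmmc_id not in group_of_bmmc:
            raise ValueError(f"assigned BMMC {bmmc_id} has no group label")
        g = group_of_bmmc[bmmc_id]
        counts[g] = counts.get(g, 0) + 1
    for g in set(group_of_bmmc.values()):
        counts.setdefault(g, 0)
    return {g: n / c_p for g, n in sorted(counts.items())}


def contribution_percentages(contributions: Mapping[str, float]) -> dict[str, float]:
    """Contributions as percentages rounded to one decimal."""
    return {g: round(100.0 * f, 1) for g, f in contributions.items()}


def compare_rates_by_group(
    m_j: Mapping[str, float],
    group_of_bmmc: Mapping[str, str],
) -> ShiftTestResult | None:
    """Two-sided Mann-Whitney test of per-BMMC rates, low vs high group."""
    low = np.array([m_j[j] for j in m_j if group_of_bmmc.get(j) == "low"])
    high = np.array([m_j[j] for j in m_j if group_of_bmmc.get(j) == "high"])
    if len(low) == 0 or len(high) == 0:
        warnings.warn("a FAM46C group has no BMMCs; rate test skipped", stacklevel=2)
        return None
    res = stats.mannwhitneyu(low, high, alternative="two-sided")
    diff = float(np.median(low) - np.median(high))
    return ShiftTestResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=int(np.sign(diff)),
    )


def export_sankey(
    assignments: Mapping[str, tuple[str, float]],
    cluster_of_bmmc: Mapping[str, int],
    group_of_cluster: Mapping[int, str],
) -> dict:
    """Three-layer node-link graph: cluster → contributor BMMC → CPC.

    Edge weight is 1 per assignment; node metadata carries the layer and
    the FAM46C group.  The dict is directly JSON-serializable and loads
    with any node-link graph reader.
    """
    matched = sorted({b for b, _ in assignments.values()})
    clusters = sorted({cluster_of_bmmc[b] for b in matched})
    nodes, links = [], []
    for t in clusters:
        nodes.append(
            {
                "id": f"C{t}",
                "layer": "cluster",
                "group": group_of_cluster.get(t),
            }
        )
    for b in matched:
        nodes.append(
            {
                "id": b,
                "layer": "bmmc",
                "group": group_of_cluster.get(cluster_of_bmmc[b]),
            }
        )
        links.append(
            {
                "source": f"C{cluster_of_bmmc[b]}",
                "target": b,
                "value": sum(1 for bb, _ in assignments.values() if bb == b),
            }
        )
    for cpc_id, (b, r) in sorted(assignments.items()):
        nodes.append({"id": cpc_id, "layer": "cpc", "group": None})
        links.append(
            {
                "source": b,
                "target": cpc_id,
                "value": 1,
                "pearson_r": r,
            }
        )
    return {"directed": True, "multigraph": False, "graph": {}, "nodes": nodes, "links": links}


def build_report(
    m: ExpressionMatrix,
    patient: str,
    labels: Mapping[str, int],
    grouping: Fam46cGrouping,
    genes: Sequence[str],
    scale: str = "log",
) -> MetastasisReport:
    """Run the full metastasis model for one patient of a matrix."""
    cpc_ids = m.cells_of(patient=patient, compartment="CPC")
    bmmc_ids = [c for c in m.cells_of(patient=patient, compartment="BMMC") if c in labels]
    if not cpc_ids or not bmmc_ids:
        raise ValueError(f"patient {patient} lacks CPCs or labeled BMMCs")
    corr = correlation_matrix(
        m.subset_cells(cpc_ids), m.subset_cells(bmmc_ids), genes, scale=scale
    )
    assignments, ties = assign_best_match(corr)
    c_j, m_j = metastasis_rates(assignments, bmmc_ids)
    cluster_of_bmmc = {b: labels[b] for b in bmmc_ids}
    group_of_bmmc = {b: grouping.group_of_cluster[labels[b]] for b in bmmc_ids}
    contributions = cluster_contributions(assignments, group_of_bmmc)
    return MetastasisReport(
        assignments=assignments,
        c_j=c_j,
        c_p=len(assignments),
        m_j=m_j,
        cluster_contribution=contributions,
        rate_comparison=compare_rates_by_group(m_j, group_of_bmmc),
        sankey=export_sankey(assignments, cluster_of_bmmc, grouping.group_of_cluster),
        tie_cpcs=ties,
        cluster_of_bmmc=cluster_of_bmmc,
        group_of_bmmc=group_of_bmmc,
    )
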