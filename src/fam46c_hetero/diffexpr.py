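"""Differential expression and whole-transcriptome level-shift tests.

Per-gene testing is a two-sided unpaired Welch t-test on FPKM with fold
change defined as ``log2((mean_a + 1) / (mean_b + 1))`` (group A the CPCs
or first cluster, group B the BMMCs or second cluster; the pseudocount
keeps the ratio stable under dropout zeros).  A gene is called
differentially expressed only *conjunctively*: it must pass both the
p-value and |log2FC| thresholds in every required patient contrast.
Benjamini-Hochberg q-values are reported alongside but play no part in
the call.

The transcriptome-level comparison summarizes each gene by its mean
log2(FPKM+1) within each cell group and tests the two resulting per-gene
distributions against each other (Kolmogorov-Smirnov for compartment
comparisons, Mann-Whitney for cluster comparisons, Welch t for
population-style comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import ExpressionMatrix

__all__ = [
    "DEGStats",
    "DEGResult",
    "ShiftTestResult",
    "gene_test",
    "call_degs",
    "transcriptome_shift",
]

SHIFT_TESTS = ("kolmogorov_smirnov", "mann_whitney", "t_test")


@dataclass(frozen=True)
class DEGStats:
    p_value: float
    log2fc: float
    mean_a: float
    mean_b: float
    q_value: float = float("nan")


@dataclass(frozen=True)
class DEGResult:
    gene: str
    per_patient: dict[str, DEGStats]
    passes_conjunctive: bool


@dataclass(frozen=True)
class ShiftTestResult:
    test_name: str
    statistic: float
    p_value: float
    direction: int  # sign of median(A) - median(B)


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    return np.log2((mean_a + 1.0) / (mean_b + 1.0))


def _welch(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Two-sided Welch t-test p-values, with degenerate rows mapped to p=1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=axis, equal_var=False)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: identical means -> no evidence (p = 1)
    return np.where(np.isfinite(p), p, 1.0)


def gene_test(
    m: ExpressionMatrix,
    gene: str,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
) -> tuple[float, float]:
    """(p_value, log2fc) of one gene between two cell groups."""
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    row = m.gene_row(gene)
    pos = {c: i for i, c in enumerate(m.cell_ids)}
    a = row[[pos[c] for c in cells_a]]
    b = row[[pos[c] for c in cells_b]]
    p = float(_welch(a, b))
    fc = float(_log2fc(a.mean(), b.mean()))
    return p, fc


def call_degs(
    m: ExpressionMatrix,
    contrasts: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    genes: Sequence[str] | None = None,
    deg_p_cutoff: float = 0.05,
    deg_abs_log2fc: float = 1.0,
    p_cutoff_overrides: Mapping[str, float] | None = None,
) -> list[DEGResult]:
    """Per-gene Welch tests across patient contrasts with the conjunctive rule.

    ``contrasts`` maps patient id -> (cells_a, cells_b).  A gene passes
    conjunctively only when p < cutoff and |log2FC| > threshold hold in
    *every* usable contrast.  A contrast with fewer than two cells in a
    group is dropped with a warning and the conjunction is taken over the
    remainder.  ``p_cutoff_overrides`` allows a stricter per-patient p
    cutoff (as used for within-patient cluster contrasts).
    """
    if not contrasts:
        raise ValueError("need at least one patient contrast")
    gene_list = list(genes) if genes is not None else list(m.gene_ids)
    gidx = [m.gene_ids.index(g) for g in gene_list] if genes is not None else None
    values = m.values if gidx is None else m.values[gidx, :]
    pos = {c: i for i, c in enumerate(m.cell_ids)}
    overrides = dict(p_cutoff_overrides or {})

    per_patient: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for patient, (cells_a, cells_b) in contrasts.items():
        if len(cells_a) < 2 or len(cells_b) < 2:
            warnings.warn(
                f"contrast {patient} has <2 cells in a group; dropped",
                stacklevel=2,
            )
            continue
        a = values[:, [pos[c] for c in cells_a]]
        b = values[:, [pos[c] for c in cells_b]]
        p = _welch(a, b, axis=1)
        q = _bh_adjust(p)
        fc = _log2fc(a.mean(axis=1), b.mean(axis=1))
        per_patient[patient] = (p, q, fc, a.mean(axis=1), b.mean(axis=1))
    if not per_patient:
        raise ValueError("no usable contrasts (all dropped)")

    results = []
    for i, gene in enumerate(gene_list):
        stats_by_patient = {}
        ok = True
        for patient, (p, q, fc, ma, mb) in per_patient.items():
            cutoff = overrides.get(patient, deg_p_cutoff)
            stats_by_patient[patient] = DEGStats(
                p_value=float(p[i]),
                q_value=float(q[i]),
                log2fc=float(fc[i]),
                mean_a=float(ma[i]),
                mean_b=float(mb[i]),
            )
            if not (p[i] < cutoff and abs(fc[i]) > deg_abs_log2fc):
                ok = False
        results.append(DEGResult(gene=gene, per_patient=stats_by_patient, passes_conjunctive=ok))
    return results


def conjunctive_genes(results: Sequence[DEGResult]) -> list[str]:
    return [r.gene for r in results if r.passes_conjunctive]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported for transparency only)."""
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def transcriptome_shift(
    m: ExpressionMatrix,
    genes: Sequence[str],
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    test_name: str = "kolmogorov_smirnov",
    per_cell: bool = False,
) -> ShiftTestResult:
    """Whole-transcriptome level comparison between two cell groups.

    Each gene in ``genes`` is summarized by its mean log2(FPKM+1) within
    each group; the two per-gene vectors are compared with the named
    two-sample test.  ``per_cell=True`` instead summarizes each *cell* by
    its mean over the genes (an alternative aggregate).
    """
    if not len(genes):
        raise ValueError("genes must be nonempty")
    if test_name not in SHIFT_TESTS:
        raise ValueError(f"unknown test {test_name!r}; choose from {SHIFT_TESTS}")
    sub = m.subset_genes(genes)
    logv = sub.log2p1()
    pos = {c: i for i, c in enumerate(sub.cell_ids)}
    a = logv[:, [pos[c] for c in cells_a]]
    b = logv[:, [pos[c] for c in cells_b]]
    va = a.mean(axis=0) if per_cell else a.mean(axis=1)
    vb = b.mean(axis=0) if per_cell else b.mean(axis=1)

    if test_name == "kolmogorov_smirnov":
        res = stats.ks_2samp(va, vb)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test_name == "mann_whitney":
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        stat = float(t) if np.isfinite(t) else 0.0
        p = float(p) if np.isfinite(p) else 1.0
    diff = float(np.median(va) - np.median(vb))
    return ShiftTestResult(
        test_name=test_name,
        statistic=stat,
        p_value=min(p, 1.0),
        direction=int(np.sign(diff)),
    )
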