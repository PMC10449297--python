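"""Cell- and transcript-level quality filters.

Cells are kept when they exceed *both* thresholds strictly: more than
``min_mapped_reads`` mapped reads and more than ``min_genes`` detected
genes.  A transcript counts as stably expressed when its FPKM exceeds the
cutoff in at least one cell (again strictly).  Both filters are idempotent
and monotone in their thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_model import ExpressionMatrix

__all__ = ["QCReport", "filter_cells", "expressed_features"]


@dataclass(frozen=True)
class QCReport:
    n_cells_in: int
    n_cells_kept: int
    kept_cell_ids: tuple[str, ...]
    n_features_in: int
    n_features_expressed: int
    min_mapped_reads: float
    min_genes: float
    expressed_fpkm_cutoff: float | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)


def filter_cells(
    m: ExpressionMatrix,
    min_mapped_reads: float = 1e5,
    min_genes: float = 1e3,
) -> tuple[ExpressionMatrix, QCReport]:
    """Keep cells with > min_mapped_reads reads AND > min_genes genes.

    ``n_genes_detected`` is taken from the metadata (the upstream pipeline's
    own count); where it is missing/NaN it is recomputed as the number of
    genes with FPKM > 0 in that cell.
    """
    reads = m.cell_meta["mapped_reads"].to_numpy(float)
    genes = m.cell_meta["n_genes_detected"].to_numpy(float)
    missing = ~np.isfinite(genes)
    if missing.any():
        genes = genes.copy()
        genes[missing] = (m.values > 0).sum(axis=0)[missing]
    keep = (reads > min_mapped_reads) & (genes > min_genes)
    kept_ids = tuple(np.asarray(m.cell_ids)[keep])
    notes: list[str] = []
    if not kept_ids:
        notes.append("no cells passed the QC thresholds")
        warnings.warn(notes[-1], stacklevel=2)
    filtered = m.subset_cells(kept_ids) if kept_ids else ExpressionMatrix(
        m.gene_ids, [], m.values[:, :0], m.cell_meta
    )
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_kept=len(kept_ids),
        kept_cell_ids=kept_ids,
        n_features_in=m.n_genes,
        n_features_expressed=m.n_genes,
        min_mapped_reads=min_mapped_reads,
        min_genes=min_genes,
        warnings=tuple(notes),
    )
    return filtered, report


def expressed_features(m: ExpressionMatrix, fpkm_cutoff: float = 1.0) -> list[str]:
    """Genes whose FPKM exceeds ``fpkm_cutoff`` in at least one cell."""
    if m.n_cells == 0:
        raise ValueError("matrix has no cells")
    keep = (m.values > fpkm_cutoff).any(axis=1)
    return [g for g, k in zip(m.gene_ids, keep) if k]
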