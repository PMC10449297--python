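"""Core data types and on-disk formats for the FPKM pipeline.

The universal carrier between stages is :class:`ExpressionMatrix`: a dense
genes x cells matrix of FPKM values plus a per-cell metadata table (patient,
compartment, mapped reads, detected genes).  The canonical on-disk format is
a tab-separated matrix (gene rows, cell columns) paired with a metadata TSV;
a MatrixMarket triple reader is provided for interoperability.

FPKM values are stored untransformed.  Every stage that needs a log scale
computes ``log2(FPKM + 1)`` on the fly and never writes it back, so the
matrix on disk is always the single source of truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "AnalysisConfig",
    "ExpressionMatrix",
    "IntegrityError",
    "ParseError",
    "read_expression_matrix",
    "read_expression_matrix_mtx",
    "write_expression_matrix",
    "write_results",
]

COMPARTMENTS = ("BMMC", "CPC")

META_COLUMNS = ("patient_id", "compartment", "mapped_reads", "n_genes_detected")


class ParseError(ValueError):
    """An input file is syntactically malformed."""


class IntegrityError(ValueError):
    """Inputs are individually well formed but mutually inconsistent."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and knobs shared by the whole pipeline.

    Defaults follow the study design: cells are kept with more than 1e5
    mapped reads and more than 1e3 detected genes; a transcript counts as
    expressed when its FPKM exceeds 1 in at least one cell; immunoglobulin
    patient specificity is called at ANOVA p < 1e-6; differential expression
    at p < 0.05 and |log2 fold change| > 1; cluster number is scanned from
    one to ten.
    """

    min_mapped_reads: float = 1e5
    min_genes: float = 1e3
    expressed_fpkm_cutoff: float = 1.0
    anova_p_cutoff: float = 1e-6
    deg_p_cutoff: float = 0.05
    deg_abs_log2fc: float = 1.0
    k_range: tuple[int, int] = (1, 10)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_mapped_reads",
            "min_genes",
            "expressed_fpkm_cutoff",
            "anova_p_cutoff",
            "deg_p_cutoff",
            "deg_abs_log2fc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.k_range
        if lo < 1 or hi < lo:
            raise ValueError("k_range must satisfy 1 <= lo <= hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d


class ExpressionMatrix:
    """Dense genes x cells FPKM matrix with per-cell metadata.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row of ``values``.
    cell_ids
        Unique cell identifiers, one per column of ``values``.
    values
        Non-negative FPKM matrix, shape ``(len(gene_ids), len(cell_ids))``.
    cell_meta
        DataFrame indexed by cell id with columns ``patient_id``,
        ``compartment`` (one of ``BMMC``/``CPC``), ``mapped_reads``,
        ``n_genes_detected``.  Rows are aligned to ``cell_ids`` order.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        values: np.ndarray,
        cell_meta: pd.DataFrame,
    ) -> None:
        gene_ids = list(map(str, gene_ids))
        cell_ids = list(map(str, cell_ids))
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise IntegrityError("duplicate gene ids")
        if len(set(cell_ids)) != len(cell_ids):
            raise IntegrityError("duplicate cell ids")
        if not np.isfinite(values).all():
            raise ValueError("non-finite FPKM value")
        if (values < 0).any():
            raise ValueError("negative FPKM value")
        missing = [c for c in cell_ids if c not in cell_meta.index]
        if missing:
            raise IntegrityError(f"cells missing from metadata: {missing[:5]}")
        for col in META_COLUMNS:
            if col not in cell_meta.columns:
                raise IntegrityError(f"metadata lacks column {col!r}")
        meta = cell_meta.loc[cell_ids, list(META_COLUMNS)].copy()
        bad = set(meta["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise IntegrityError(f"unknown compartment labels: {sorted(bad)}")
        self.gene_ids = gene_ids
        self.cell_ids = cell_ids
        self.values = values
        self.cell_meta = meta
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_row(self, gene: str) -> np.ndarray:
        """FPKM values of one gene across all cells."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def log2p1(self) -> np.ndarray:
        """``log2(FPKM + 1)``, the working scale of all downstream stages."""
        return np.log2(self.values + 1.0)

    # -- subsetting ----------------------------------------------------------

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes]
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(genes, self.cell_ids, self.values[idx, :], self.cell_meta)

    def subset_cells(self, cells: Iterable[str]) -> "ExpressionMatrix":
        cells = [c for c in cells]
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in cells]
        return ExpressionMatrix(self.gene_ids, cells, self.values[:, idx], self.cell_meta)

    def cells_of(
        self, patient: str | None = None, compartment: str | None = None
    ) -> list[str]:
        """Cell ids matching the given patient and/or compartment."""
        mask = pd.Series(True, index=self.cell_meta.index)
        if patient is not None:
            mask &= self.cell_meta["patient_id"] == patient
        if compartment is not None:
            mask &= self.cell_meta["compartment"] == compartment
        return list(self.cell_meta.index[mask])

    @property
    def patients(self) -> list[str]:
        return sorted(self.cell_meta["patient_id"].unique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells, "
            f"patients={self.patients})"
        )


def concat_cells(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate matrices sharing one gene list (e.g. a patient cohort)."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise IntegrityError("matrices have different gene lists")
    cells = [c for m in matrices for c in m.cell_ids]
    values = np.hstack([m.values for m in matrices])
    meta = pd.concat([m.cell_meta for m in matrices])
    return ExpressionMatrix(genes, cells, values, meta)


# -- readers / writers -------------------------------------------------------


def _read_meta(meta_path: str | Path) -> pd.DataFrame:
    try:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse metadata TSV {meta_path}: {exc}") from exc
    required = ("cell_id",) + META_COLUMNS
    for col in required:
        if col not in meta.columns:
            raise ParseError(f"metadata TSV {meta_path} lacks column {col!r}")
    if meta["cell_id"].duplicated().any():
        raise IntegrityError("duplicate cell_id in metadata")
    return meta.set_index("cell_id")


def read_expression_matrix(
    matrix_path: str | Path, meta_path: str | Path
) -> ExpressionMatrix:
    """Read the canonical TSV pair (gene-rows matrix + per-cell metadata).

    The matrix header row carries the cell ids; the first column carries gene
    symbols.  Every cell column must have a metadata row; missing metadata is
    an :class:`IntegrityError`, a negative FPKM a :class:`ValueError`, and a
    malformed table a :class:`ParseError` naming the offending line.
    """
    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse matrix TSV {matrix_path}: {exc}") from exc
    non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(non_numeric):
        for line_no, (_, row) in enumerate(df[non_numeric].iterrows(), start=2):
            bad = row[pd.to_numeric(row, errors="coerce").isna()]
            if len(bad):
                raise ParseError(
                    f"non-numeric value {bad.iloc[0]!r} at line {line_no} "
                    f"of {matrix_path}"
                )
        df[non_numeric] = df[non_numeric].astype(float)
    meta = _read_meta(meta_path)
    missing = [c for c in df.columns if c not in meta.index]
    if missing:
        raise IntegrityError(
            f"cells present in matrix but absent from metadata: {missing[:5]}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(float), meta)


def read_expression_matrix_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
) -> ExpressionMatrix:
    """Read a MatrixMarket triple (matrix.mtx + genes.tsv + barcodes.tsv)."""
    from scipy.io import mmread

    try:
        values = np.asarray(mmread(str(mtx_path)).todense(), dtype=float)
    except Exception as exc:
        raise ParseError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    genes = [ln.split("\t")[0].strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    cells = [ln.split("\t")[0].strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    return ExpressionMatrix(genes, cells, values, _read_meta(meta_path))


def write_expression_matrix(
    m: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path
) -> None:
    """Write the canonical TSV pair; inverse of :func:`read_expression_matrix`."""
    df = m.to_frame()
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = m.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.to_csv(meta_path, sep="\t")


def _result_rows(bundle) -> list[dict]:
    return [dataclasses.asdict(r) for r in bundle]


def write_results(bundle, out_dir: str | Path) -> dict[str, int]:
    """Serialize a result object (or list of records) under ``out_dir``.

    Dispatches on the result type and returns a manifest mapping each file
    written to its record count.  The manifest is also appended to
    ``manifest.json`` in the run directory.
    """
    # imported here to avoid circular imports between stage modules
    from .clustering import ClusterModel, Fam46cGrouping
    from .diffexpr import DEGResult, ShiftTestResult
    from .metastasis import MetastasisReport
    from .qc_filter import QCReport
    from .specificity import IgSpecificityResult

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    def _write_json(name: str, obj, n: int) -> None:
        with open(out / name, "w") as fh:
            json.dump(obj, fh, indent=1, default=_json_default)
        manifest[name] = n

    def _write_tsv(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, sep="\t", index=False)
        manifest[name] = len(df)

    if isinstance(bundle, QCReport):
        _write_json("qc_report.json", dataclasses.asdict(bundle), bundle.n_cells_kept)
    elif isinstance(bundle, MetastasisReport):
        _write_tsv("rates.tsv", bundle.rates_table())
        _write_json("contributions.json", bundle.cluster_contribution, len(bundle.cluster_contribution))
        _write_json("sankey.json", bundle.sankey, len(bundle.sankey.get("nodes", [])))
    elif isinstance(bundle, ClusterModel):
        _write_tsv("clusters.tsv", bundle.labels_table())
        _write_tsv("silhouette.tsv", bundle.silhouette_table())
    elif isinstance(bundle, Fam46cGrouping):
        _write_json("grouping.json", dataclasses.asdict(bundle), len(bundle.group_of_cluster))
    elif isinstance(bundle, ShiftTestResult):
        _write_json("shift_test.json", dataclasses.asdict(bundle), 1)
    elif isinstance(bundle, list) and all(isinstance(r, IgSpecificityResult) for r in bundle) and (
        bundle and isinstance(bundle[0], IgSpecificityResult)
    ):
        rows = _result_rows(bundle)
        for r in rows:
            r["specific_patients"] = ",".join(r["specific_patients"])
            r["per_patient_mean"] = json.dumps(r["per_patient_mean"])
        _write_tsv("specificity.tsv", pd.DataFrame(rows))
    elif isinstance(bundle, list) and (not bundle or isinstance(bundle[0], DEGResult)):
        rows = []
        for r in bundle:
            for patient, stats in r.per_patient.items():
                rows.append(
                    {
                        "gene": r.gene,
                        "patient": patient,
                        "p_value": stats.p_value,
                        "q_value": stats.q_value,
                        "log2fc": stats.log2fc,
                        "mean_a": stats.mean_a,
                        "mean_b": stats.mean_b,
                        "passes_conjunctive": r.passes_conjunctive,
                    }
                )
        cols = [
            "gene", "patient", "p_value", "q_value", "log2fc",
            "mean_a", "mean_b", "passes_conjunctive",
        ]
        _write_tsv("degs.tsv", pd.DataFrame(rows, columns=cols))
    else:
        raise TypeError(f"no serializer for result of type {type(bundle).__name__}")

    mpath = out / "manifest.json"
    merged = {}
    if mpath.exists():
        merged = json.loads(mpath.read_text())
    merged.update(manifest)
    with open(mpath, "w") as fh:
        json.dump(merged, fh, indent=1)
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
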