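"""Patient-specific immunoglobulin gene expression.

In multiple myeloma each patient's malignant plasma-cell clone transcribes
a characteristic set of immunoglobulin (Ig) variable-segment and constant
genes.  This module detects Ig genes by symbol nomenclature (IGH/IGK/IGL
prefixes) and calls a gene patient-specific when a one-way ANOVA of its
FPKM values across patients is significant at a very stringent cutoff
(default p < 1e-6).

Which patient(s) a significant gene belongs to is decided by an outlier
rule on the per-patient means: patient p is listed when its mean exceeds
the mean of the *other* patients' means by more than two of their standard
deviations (for two patients, simply the larger mean).  More than one
patient can qualify, as shared clonotypic genes do occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_model import ExpressionMatrix

__all__ = [
    "IG_PREFIXES",
    "IgSpecificityResult",
    "identify_ig_genes",
    "anova_specificity",
    "specificity_table",
]

IG_PREFIXES = ("IGH", "IGK", "IGL")


@dataclass(frozen=True)
class IgSpecificityResult:
    gene: str
    per_patient_mean: dict[str, float]
    f_statistic: float
    p_value: float
    is_specific: bool
    specific_patients: tuple[str, ...] = field(default_factory=tuple)


def identify_ig_genes(gene_ids: list[str]) -> list[str]:
    """Genes whose symbol starts with an immunoglobulin locus prefix."""
    return [g for g in gene_ids if g.upper().startswith(IG_PREFIXES)]


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA; degenerate all-equal input gives F=0, p=1."""
    concat = np.concatenate(groups)
    if np.ptp(concat) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance with equal means etc.
        return 0.0, 1.0
    return float(f), float(p)


def _specific_patients(means: dict[str, float]) -> tuple[str, ...]:
    """Patients whose mean stands out above the remaining patients' means.

    Leave-one-out outlier rule: patient p qualifies when
    mean_p > mean(others) + 2 * sd(others).  With only two patients the
    larger mean qualifies.  Ties can list several patients.
    """
    names = list(means)
    out = []
    for p in names:
        others = np.array([means[q] for q in names if q != p], dtype=float)
        if len(others) == 1:
            if means[p] > others[0]:
                out.append(p)
            continue
        mu = others.mean()
        sd = others.std(ddof=1)
        if means[p] > mu + 2.0 * sd:
            out.append(p)
    return tuple(out)


def anova_specificity(
    m: ExpressionMatrix,
    gene: str,
    anova_p_cutoff: float = 1e-6,
    use_log: bool = False,
) -> IgSpecificityResult:
    """One-way ANOVA of one gene's FPKM grouped by patient.

    ANOVA is computed on raw FPKM by default (the scale on which the values
    are reported); ``use_log`` switches to log2(FPKM+1).  Patients with
    fewer than two cells are excluded with a warning.  Dropout zeros are
    ordinary observations.
    """
    row = m.gene_row(gene)
    if use_log:
        row = np.log2(row + 1.0)
    patients = m.cell_meta["patient_id"].to_numpy()
    groups, means = [], {}
    for p in sorted(set(patients)):
        vals = row[patients == p]
        if len(vals) < 2:
            warnings.warn(f"patient {p} has <2 cells; excluded from ANOVA", stacklevel=2)
            continue
        groups.append(vals)
        means[p] = float(vals.mean())
    if len(groups) < 2:
        raise ValueError("need at least two patients with >=2 cells")
    f, p_value = _one_way_anova(groups)
    is_specific = p_value < anova_p_cutoff
    return IgSpecificityResult(
        gene=gene,
        per_patient_mean=means,
        f_statistic=f,
        p_value=p_value,
        is_specific=is_specific,
        specific_patients=_specific_patients(means) if is_specific else (),
    )


def specificity_table(
    m: ExpressionMatrix,
    anova_p_cutoff: float = 1e-6,
    genes: list[str] | None = None,
    use_log: bool = False,
) -> list[IgSpecificityResult]:
    """ANOVA specificity for every (detected) Ig gene, sorted by p ascending.

    ``genes`` restricts the candidate pool (e.g. to the expressed-feature
    set); by default all Ig genes present in the matrix are tested.
    """
    pool = genes if genes is not None else m.gene_ids
    results = [
        anova_specificity(m, g, anova_p_cutoff=anova_p_cutoff, use_log=use_log)
        for g in identify_ig_genes(list(pool))
    ]
    return sorted(results, key=lambda r: (r.p_value, r.gene))
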