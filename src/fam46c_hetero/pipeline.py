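"""End-to-end orchestration: QC → specificity → DEGs → clustering → metastasis.

The stages are pure functions of (inputs, config, seed); a run writes its
outputs plus a manifest (config snapshot, input hashes, stage list, seed,
version) under a timestamp-free directory so repeated runs diff cleanly.

Clustering features are the conjunctive DEG set united with the detected
immunoglobulin genes.  When no DEG contrast is possible (a patient with no
CPCs, or a single-compartment matrix) the top-500-variance expressed genes
substitute, and the manifest says so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .clustering import (
    ClusterModel,
    Fam46cGrouping,
    feature_matrix,
    label_fam46c_groups,
    select_k_silhouette,
)
from .diffexpr import DEGResult, call_degs, conjunctive_genes
from .io_model import AnalysisConfig, ExpressionMatrix, write_results
from .metastasis import MetastasisReport, build_report
from .qc_filter import QCReport, expressed_features, filter_cells
from .specificity import IgSpecificityResult, identify_ig_genes, specificity_table

log = logging.getLogger("fam46c_hetero")

__all__ = ["PatientResult", "RunManifest", "run_patient", "run_all"]

FALLBACK_TOP_VARIANCE = 500


@dataclass
class PatientResult:
    patient_id: str
    qc: QCReport
    expressed_genes: list[str]
    cluster_model: ClusterModel
    grouping: Fam46cGrouping
    metastasis: MetastasisReport | None
    feature_source: str  # "degs+ig" or "top_variance+ig"


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_hashes: dict[str, str]
    stage_seconds: dict[str, float]
    outputs: list[str]
    notes: list[str] = field(default_factory=list)


def _deg_contrasts(
    m: ExpressionMatrix, patients: Sequence[str]
) -> dict[str, tuple[list[str], list[str]]]:
    """CPC-vs-BMMC contrast per patient, keeping only usable ones."""
    contrasts = {}
    for p in patients:
        cpc = m.cells_of(patient=p, compartment="CPC")
        bmmc = m.cells_of(patient=p, compartment="BMMC")
        if len(cpc) >= 2 and len(bmmc) >= 2:
            contrasts[p] = (cpc, bmmc)
    return contrasts


def _clustering_features(
    m: ExpressionMatrix,
    expressed: list[str],
    deg_genes: list[str],
) -> tuple[list[str], str]:
    ig = identify_ig_genes(expressed)
    if deg_genes:
        feats = sorted(set(deg_genes) | set(ig))
        return feats, "degs+ig"
    sub = m.subset_genes(expressed)
    var = sub.log2p1().var(axis=1)
    order = np.argsort(var)[::-1][:FALLBACK_TOP_VARIANCE]
    top = [expressed[i] for i in sorted(order)]
    log.warning(
        "no DEG set available; falling back to top-%d-variance genes for clustering",
        FALLBACK_TOP_VARIANCE,
    )
    return sorted(set(top) | set(ig)), "top_variance+ig"


def run_patient(
    m: ExpressionMatrix,
    patient: str,
    config: AnalysisConfig = AnalysisConfig(),
    deg_genes: Sequence[str] | None = None,
) -> PatientResult:
    """Full per-patient analysis of one (possibly multi-patient) matrix.

    ``deg_genes`` injects a DEG set defined elsewhere (e.g. the conjunctive
    cross-patient set); when None, the patient's own CPC-vs-BMMC contrast
    is used, with a top-variance fallback if no contrast is possible.
    """
    cells = m.cells_of(patient=patient)
    mp = m.subset_cells(cells)
    mp, qc = filter_cells(mp, config.min_mapped_reads, config.min_genes)
    if mp.n_cells == 0:
        raise ValueError(f"patient {patient}: no cells pass QC")
    expressed = expressed_features(mp, config.expressed_fpkm_cutoff)
    mp = mp.subset_genes(expressed)

    if deg_genes is None:
        contrasts = _deg_contrasts(mp, [patient])
        if contrasts:
            results = call_degs(
                mp,
                contrasts,
                deg_p_cutoff=config.deg_p_cutoff,
                deg_abs_log2fc=config.deg_abs_log2fc,
            )
            deg_genes = conjunctive_genes(results)
        else:
            deg_genes = []
    deg_genes = [g for g in deg_genes if g in set(expressed)]

    feats, source = _clustering_features(mp, expressed, list(deg_genes))
    bmmc = mp.cells_of(compartment="BMMC")
    mb = mp.subset_cells(bmmc)
    z, kept = feature_matrix(mb, feats)
    model = select_k_silhouette(z, mb.cell_ids, config.k_range, tuple(kept))
    grouping = label_fam46c_groups(mp, model.labels)

    report = None
    if mp.cells_of(compartment="CPC"):
        report = build_report(mp, patient, model.labels, grouping, expressed)
    return PatientResult(
        patient_id=patient,
        qc=qc,
        expressed_genes=expressed,
        cluster_model=model,
        grouping=grouping,
        metastasis=report,
        feature_source=source,
    )


def run_all(
    m: ExpressionMatrix,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir: str | Path | None = None,
    input_paths: Sequence[str | Path] = (),
) -> tuple[dict[str, PatientResult], list[IgSpecificityResult], list[DEGResult], RunManifest]:
    """Run every stage on a cohort matrix and optionally write all reports.

    Order: QC → Ig specificity (needs ≥2 patients) → conjunctive DEGs over
    every patient with both compartments → per-patient clustering, FAM46C
    grouping and metastasis.  Stages whose preconditions fail are skipped
    with a log line and the run continues.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    notes: list[str] = []

    mq, qc = filter_cells(m, config.min_mapped_reads, config.min_genes)
    if mq.n_cells == 0:
        raise ValueError("no cells pass QC")
    expressed = expressed_features(mq, config.expressed_fpkm_cutoff)
    mq = mq.subset_genes(expressed)
    timings["qc"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    spec_results: list[IgSpecificityResult] = []
    if len(mq.patients) >= 2:
        spec_results = specificity_table(mq, config.anova_p_cutoff)
    else:
        notes.append("specificity skipped: fewer than two patients")
        log.info(notes[-1])
    timings["specificity"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    contrasts = _deg_contrasts(mq, mq.patients)
    deg_results: list[DEGResult] = []
    deg_set: list[str] = []
    if contrasts:
        deg_results = call_degs(
            mq,
            contrasts,
            deg_p_cutoff=config.deg_p_cutoff,
            deg_abs_log2fc=config.deg_abs_log2fc,
        )
        deg_set = conjunctive_genes(deg_results)
    else:
        notes.append("DEG stage skipped: no patient has both compartments")
        log.info(notes[-1])
    timings["diffexpr"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    per_patient: dict[str, PatientResult] = {}
    for p in mq.patients:
        try:
            per_patient[p] = run_patient(
                m, p, config, deg_genes=deg_set if deg_set else None
            )
        except ValueError as exc:
            notes.append(f"patient {p} skipped: {exc}")
            log.warning(notes[-1])
    timings["per_patient"] = time.perf_counter() - t3

    outputs: list[str] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_files = write_results(qc, out)
        outputs += list(manifest_files)
        if spec_results:
            outputs += list(write_results(spec_results, out))
        if deg_results:
            outputs += list(write_results(deg_results, out))
        for p, res in per_patient.items():
            pdir = out / p
            outputs += [f"{p}/{f}" for f in write_results(res.cluster_model, pdir)]
            outputs += [f"{p}/{f}" for f in write_results(res.grouping, pdir)]
            if res.metastasis is not None:
                outputs += [f"{p}/{f}" for f in write_results(res.metastasis, pdir)]

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.rng_seed,
        version=__version__,
        input_hashes={str(p): _sha256(p) for p in input_paths},
        stage_seconds={k: round(v, 4) for k, v in timings.items()},
        outputs=sorted(outputs),
        notes=notes,
    )
    if out_dir is not None:
        with open(Path(out_dir) / "run_manifest.json", "w") as fh:
            json.dump(dataclasses.asdict(manifest), fh, indent=1)
    return per_patient, spec_results, deg_results, manifest


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
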