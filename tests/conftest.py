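import numpy as np
import pandas as pd
import pytest

from fam46c_hetero import (
    ExpressionMatrix,
    generate_patient,
    scenario_p17,
    scenario_p20,
)
from fam46c_hetero.pipeline import run_patient


def make_matrix(values, gene_ids=None, cell_ids=None, patients=None,
                compartments=None, mapped_reads=None, n_genes_detected=None):
    """Small hand-built ExpressionMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "patient_id": patients or ["P1"] * n_cells,
            "compartment": compartments or ["BMMC"] * n_cells,
            "mapped_reads": mapped_reads or [10**6] * n_cells,
            "n_genes_detected": n_genes_detected or [5000] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return ExpressionMatrix(gene_ids, cell_ids, values, meta)


@pytest.fixture(scope="session")
def p17_case():
    """One generated P17 scenario with its ground truth (seed fixed)."""
    return generate_patient(scenario_p17(seed=11))


@pytest.fixture(scope="session")
def p20_case():
    return generate_patient(scenario_p20(seed=11))


@pytest.fixture(scope="session")
def p17_result(p17_case):
    """Full pipeline result on the session P17 case."""
    m, _ = p17_case
    return run_patient(m, "P17")
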