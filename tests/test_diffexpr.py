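import numpy as np
import pytest
from scipy import stats

from fam46c_hetero import generate_cohort, generate_patient, scenario_p17, scenario_p20
from fam46c_hetero.diffexpr import (
    call_degs,
    conjunctive_genes,
    gene_test,
    transcriptome_shift,
)
from fam46c_hetero.qc_filter import expressed_features

from conftest import make_matrix


def welch_oracle(a, b):
    """Hand-coded Welch t statistic and two-sided p."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return t, 2 * stats.t.sf(abs(t), df)


def two_group_matrix(a, b):
    vals = np.concatenate([a, b])[None, :]
    comps = ["CPC"] * len(a) + ["BMMC"] * len(b)
    return make_matrix(vals, gene_ids=["G"], compartments=comps), \
        [f"c{i}" for i in range(len(a))], \
        [f"c{i}" for i in range(len(a), len(a) + len(b))]


def test_log2fc_of_means_with_pseudocount():
    m, ca, cb = two_group_matrix(np.array([3.0, 3, 3]), np.array([1.0, 1, 1]))
    _, fc = gene_test(m, "G", ca, cb)
    assert fc == pytest.approx(1.0)  # log2(4/2)


def test_identical_groups_p_one_fc_zero():
    m, ca, cb = two_group_matrix(np.array([2.0, 2, 2]), np.array([2.0, 2, 2]))
    p, fc = gene_test(m, "G", ca, cb)
    assert p == 1.0 and fc == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_welch_matches_formula_oracle(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.gamma(2, 3, 15), rng.gamma(3, 2, 15)
    m, ca, cb = two_group_matrix(a, b)
    p, fc = gene_test(m, "G", ca, cb)
    _, p_oracle = welch_oracle(a, b)
    assert p == pytest.approx(p_oracle, rel=1e-10)
    assert fc == pytest.approx(np.log2((a.mean() + 1) / (b.mean() + 1)), rel=1e-12)


def test_log2fc_antisymmetry():
    rng = np.random.default_rng(4)
    a, b = rng.gamma(2, 3, 10), rng.gamma(2, 3, 12)
    m, ca, cb = two_group_matrix(a, b)
    _, fc_ab = gene_test(m, "G", ca, cb)
    _, fc_ba = gene_test(m, "G", cb, ca)
    assert fc_ab == pytest.approx(-fc_ba, abs=1e-12)


def test_single_patient_reduces_to_threshold_filter(p17_case):
    """call_degs with one contrast equals direct thresholding of gene_test."""
    m, _ = p17_case
    genes = expressed_features(m, 1.0)[:120]
    cpc, bmmc = m.cells_of(compartment="CPC"), m.cells_of(compartment="BMMC")
    results = call_degs(m, {"P17": (cpc, bmmc)}, genes=genes)
    called = set(conjunctive_genes(results))
    oracle = set()
    for g in genes:
        p, fc = gene_test(m, g, cpc, bmmc)
        if p < 0.05 and abs(fc) > 1:
            oracle.add(g)
    assert called == oracle


def test_gene_passing_one_patient_only_fails_conjunction(p17_case):
    m17, truth = p17_case
    m20, _ = generate_patient(scenario_p20(seed=11))
    # patient P20's contrast replaced by a null: same compartment twice
    from fam46c_hetero.io_model import concat_cells

    m = concat_cells([m17, m20])
    gene = truth.planted_deg_genes[0]
    bmmc20 = m.cells_of(patient="P20", compartment="BMMC")
    contrasts = {
        "P17": (m.cells_of(patient="P17", compartment="CPC"),
                m.cells_of(patient="P17", compartment="BMMC")),
        "P20": (bmmc20[:10], bmmc20[10:]),  # null contrast
    }
    results = {r.gene: r for r in call_degs(m, contrasts, genes=[gene])}
    r = results[gene]
    assert r.per_patient["P17"].p_value < 0.05
    assert abs(r.per_patient["P17"].log2fc) > 1
    assert not r.passes_conjunctive


def test_small_contrast_dropped_with_warning(p17_case):
    m, _ = p17_case
    contrasts = {
        "P17": (m.cells_of(compartment="CPC"), m.cells_of(compartment="BMMC")),
        "PX": (["P17-B000"], m.cells_of(compartment="BMMC")),
    }
    with pytest.warns(UserWarning, match="dropped"):
        results = call_degs(m, contrasts, genes=m.gene_ids[:5])
    assert set(results[0].per_patient) == {"P17"}


def test_planted_deg_recovery_sensitivity_and_fdp():
    """Conjunctive calls recover the planted shifted genes with few extras."""
    sens, fdp = [], []
    for seed in range(1, 11):
        m, truths = generate_cohort(
            [scenario_p17(seed=seed), scenario_p20(seed=seed + 1000)]
        )
        expr = expressed_features(m, 1.0)
        contrasts = {
            p: (m.cells_of(patient=p, compartment="CPC"),
                m.cells_of(patient=p, compartment="BMMC"))
            for p in ("P17", "P20")
        }
        calls = set(conjunctive_genes(call_degs(m, contrasts, genes=expr)))
        planted = (set(truths["P17"].planted_deg_genes) | {"FAM46C"}) & set(expr)
        tp = len(calls & planted)
        sens.append(tp / len(planted))
        fdp.append((len(calls) - tp) / max(len(calls), 1))
    assert np.median(sens) >= 0.85
    assert np.median(fdp) <= 0.10


def test_null_simulation_few_conjunctive_calls():
    """No planted effects: conjunctive calls stay around the nominal level."""
    rates = []
    for seed in range(1, 11):
        null = dict(n_deg_genes=0, cpc_fam46c_log2_shift=0.0,
                    fam46c_low_log2_shift=0.0, global_low_scale=1.0)
        m, _ = generate_cohort(
            [scenario_p17(seed=seed, **null), scenario_p20(seed=seed + 500, **null)]
        )
        expr = expressed_features(m, 1.0)
        contrasts = {
            p: (m.cells_of(patient=p, compartment="CPC"),
                m.cells_of(patient=p, compartment="BMMC"))
            for p in ("P17", "P20")
        }
        calls = conjunctive_genes(call_degs(m, contrasts, genes=expr))
        rates.append(len(calls) / len(expr))
    assert np.mean(rates) <= 0.01


def test_shift_identity_and_disjoint_ks():
    m = make_matrix(np.tile(np.array([1.0, 2, 3])[:, None], (1, 6)))
    res = transcriptome_shift(m, m.gene_ids, m.cell_ids[:3], m.cell_ids[3:])
    assert res.p_value >= 0.99 and res.direction == 0
    # KS D = 1 on disjoint supports
    vals = np.array([[1.0, 2, 3, 40, 50, 60]])
    m2 = make_matrix(vals, gene_ids=["G"])
    from scipy.stats import ks_2samp

    d = ks_2samp(np.log2(vals[0, :3] + 1), np.log2(vals[0, 3:] + 1)).statistic
    assert d == 1.0


def test_unknown_shift_test_rejected(p17_case):
    m, _ = p17_case
    with pytest.raises(ValueError, match="unknown test"):
        transcriptome_shift(m, m.gene_ids[:5], m.cell_ids[:3], m.cell_ids[3:6], "anova")


def test_shift_direction_negative_under_global_scale(p17_case):
    """All three tests see the planted transcriptome depression, same sign."""
    m, truth = p17_case
    genes = expressed_features(m, 1.0)
    low = [c for c, t in truth.bmmc_cluster_of_cell.items() if t in (0, 2)]
    high = [c for c, t in truth.bmmc_cluster_of_cell.items() if t == 1]
    results = [
        transcriptome_shift(m, genes, low, high, name)
        for name in ("kolmogorov_smirnov", "mann_whitney", "t_test")
    ]
    assert all(r.direction == -1 for r in results)
    assert all(r.p_value < 0.01 for r in results)
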