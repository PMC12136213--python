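"""Signature scores, state gating, meta-cells and composition tables."""

import numpy as np
import pandas as pd
import pytest

import tregdegron as td
from tregdegron.containers import ExpressionMatrix, FormatError
from tregdegron.scoring import MetaCell, metacell_expression, metacell_score

from conftest import dense_counts


def expr(arr):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        arr, [f"c{i}" for i in range(arr.shape[0])],
        [f"g{j}" for j in range(arr.shape[1])],
    )


# ---------------------------------------------------------------------------
# signature score
# ---------------------------------------------------------------------------

def test_score_closed_form_on_degenerate_matrix():
    """Signature at constant c over constant background b scores c - b."""
    mat = np.full((6, 30), 2.0)
    mat[:, :5] = 7.0
    e = expr(mat)
    score = td.signature_score(e, [f"g{j}" for j in range(5)], n_bins=1, ctrl_size=10)
    assert np.allclose(score, 5.0)


def test_score_null_for_background_matched_signature():
    rng = np.random.default_rng(0)
    mat = rng.gamma(2.0, 1.0, size=(200, 300))
    e = expr(mat)
    sig = [f"g{j}" for j in rng.choice(300, size=25, replace=False)]
    score = td.signature_score(e, sig, n_bins=10, ctrl_size=50, seed=3)
    assert abs(float(score.mean())) < 0.1


def test_score_drops_missing_genes_but_rejects_empty():
    e = expr(np.ones((3, 4)))
    s = td.signature_score(e, ["g0", "not_a_gene"], n_bins=1, ctrl_size=2)
    assert np.isfinite(s).all()
    with pytest.raises(FormatError):
        td.signature_score(e, ["nope"], n_bins=1, ctrl_size=2)


def test_planted_state_markers_separate_states(small_config, small_truth, small_dataset):
    counts, cells = small_dataset
    norm = td.normalize_counts(counts)
    score = td.signature_score(norm, small_truth.state_markers["activated"], seed=5)
    by_state = score.groupby(cells.set_index("cell_id")["state"]).mean()
    assert by_state["activated"] > by_state["resting"]


# ---------------------------------------------------------------------------
# state classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rest,act,expected",
    [(0.5, -0.2, "resting"), (-0.2, 0.5, "activated"),
     (0.5, 0.5, "unassigned"), (-0.1, -0.1, "unassigned")],
)
def test_classification_rule(rest, act, expected):
    s = td.classify_states(
        pd.Series({"c": rest}), pd.Series({"c": act}), (0.0, 0.0)
    )
    assert s["c"] == expected


def test_classification_shift_invariance():
    rng = np.random.default_rng(2)
    idx = [f"c{i}" for i in range(100)]
    a = pd.Series(rng.normal(size=100), index=idx)
    b = pd.Series(rng.normal(size=100), index=idx)
    base = td.classify_states(a, b, (0.1, -0.2))
    shifted = td.classify_states(a + 3.5, b + 3.5, (3.6, 3.3))
    assert (base == shifted).all()


def test_state_recovery_on_synthetic_data(small_config, small_truth, small_dataset):
    counts, cells = small_dataset
    norm = td.normalize_counts(counts)
    sr = td.signature_score(norm, small_truth.state_markers["resting"], seed=1)
    sa = td.signature_score(norm, small_truth.state_markers["activated"], seed=2)
    called = td.classify_states(sr, sa)
    truth = cells.set_index("cell_id").loc[called.index, "state"]
    assert (called.to_numpy() == truth.to_numpy()).mean() >= 0.8


# ---------------------------------------------------------------------------
# meta-cells
# ---------------------------------------------------------------------------

def test_metacells_partition_cells():
    rng = np.random.default_rng(3)
    e = expr(rng.normal(size=(100, 40)))
    groups = pd.Series("all", index=e.cell_ids)
    mcs = td.build_metacells(e, groups, target_size=20, seed=0)
    assert len(mcs) == 5
    members = [c for m in mcs for c in m.member_cells]
    assert sorted(members) == sorted(e.cell_ids)


def test_metacells_identical_cells_identical_means():
    e = expr(np.tile(np.arange(6.0), (40, 1)))
    mcs = td.build_metacells(e, pd.Series("s", index=e.cell_ids), target_size=10, seed=0)
    for m in mcs:
        assert np.allclose(m.mean_expression, np.arange(6.0))


def test_metacells_conserve_expression_sums():
    rng = np.random.default_rng(4)
    e = expr(rng.gamma(2, 1, size=(75, 20)))
    groups = pd.Series(["a"] * 40 + ["b"] * 35, index=e.cell_ids)
    mcs = td.build_metacells(e, groups, target_size=12, seed=1)
    dense = e.to_dense()
    for stratum in ("a", "b"):
        sel = [m for m in mcs if m.metacell_id.startswith(stratum)]
        agg = sum(m.size * m.mean_expression for m in sel)
        rows = np.flatnonzero((groups == stratum).to_numpy())
        assert np.allclose(agg, dense[rows].sum(axis=0), atol=1e-6)


def test_small_stratum_becomes_single_metacell():
    e = expr(np.random.default_rng(5).normal(size=(7, 5)))
    mcs = td.build_metacells(e, pd.Series("tiny", index=e.cell_ids), target_size=20)
    assert len(mcs) == 1 and mcs[0].size == 7


# ---------------------------------------------------------------------------
# dose-response correlation
# ---------------------------------------------------------------------------

def _toy_metacells(n=6):
    rng = np.random.default_rng(6)
    mats = rng.gamma(2, 1, size=(n, 10))
    mats[:, 0] = np.linspace(1, 4, n)  # anchor gradient
    return [
        MetaCell(f"m{i}", [f"c{i}"], mats[i]) for i in range(n)
    ], [f"g{j}" for j in range(10)]


def test_dose_correlation_self_and_anti():
    mcs, genes = _toy_metacells()
    anchor = pd.Series([m.mean_expression[0] for m in mcs],
                       index=[m.metacell_id for m in mcs])
    r, _ = td.metacell_dose_correlation(mcs, genes, "g0", anchor)
    assert r == pytest.approx(1.0)
    r, _ = td.metacell_dose_correlation(mcs, genes, "g0", -anchor)
    assert r == pytest.approx(-1.0)


def test_dose_correlation_rejects_zero_variance():
    mcs, genes = _toy_metacells()
    flat = pd.Series(1.0, index=[m.metacell_id for m in mcs])
    with pytest.raises(FormatError):
        td.metacell_dose_correlation(mcs, genes, "g0", flat)


def test_dose_correlation_recovers_planted_signs():
    """Across degrader meta-cells, the module repressed by the TF tracks the
    anchor negatively and the activated module positively."""
    cfg = td.SimulationConfig(n_cells_per_group=60, seed=31)
    truth = td.make_ground_truth(cfg)
    counts, cells = td.simulate_cells(truth, cfg)
    norm = td.normalize_counts(counts)
    degr = cells[cells["genotype"] == "degrader"]
    sub = norm.subset_cells(np.isin(np.array(norm.cell_ids), degr["cell_id"].to_numpy()))
    strata = pd.Series(
        (degr["sample"] + "|" + degr["state"]).to_numpy(), index=degr["cell_id"]
    ).reindex(sub.cell_ids)
    mcs = td.build_metacells(sub, strata, target_size=20, seed=0)
    anchor = truth.anchor_gene
    tir1_down = [g for g in truth.module_genes("direct_activated") if g != anchor]
    tir1_up = truth.module_genes("direct_repressed")
    r_down, _ = td.metacell_dose_correlation(
        mcs, norm.gene_ids, anchor, metacell_score(mcs, norm.gene_ids, tir1_down))
    r_up, _ = td.metacell_dose_correlation(
        mcs, norm.gene_ids, anchor, metacell_score(mcs, norm.gene_ids, tir1_up))
    assert r_down > 0.5
    assert r_up < -0.5


# ---------------------------------------------------------------------------
# cluster composition
# ---------------------------------------------------------------------------

def test_cluster_composition_counting_oracle():
    rng = np.random.default_rng(7)
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(200)],
            "genotype": rng.choice(["control", "degrader"], size=200),
            "day": rng.choice([0, 3, 7], size=200),
            "cluster": rng.integers(0, 4, size=200),
        }
    )
    comp = td.cluster_composition(meta)
    assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-12)
    for cl in comp.index:
        sub = meta[meta["cluster"] == cl]
        for col in comp.columns:
            expected = ((sub["genotype"] == col[0]) & (sub["day"] == col[1])).sum()
            assert comp.loc[cl, col] == pytest.approx(expected / len(sub))


def test_single_cluster_matches_global_fractions():
    meta = pd.DataFrame(
        {"cell_id": ["a", "b", "c", "d"],
         "genotype": ["control", "control", "degrader", "degrader"],
         "day": [0, 0, 0, 7], "cluster": [1, 1, 1, 1]}
    )
    comp = td.cluster_composition(meta)
    assert comp.loc[1, ("control", 0)] == 0.5
    assert comp.loc[1, ("degrader", 7)] == 0.25
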