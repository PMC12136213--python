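"""Generator contracts: module partitions, planted effects, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tregdegron as td
from tregdegron.config import ConfigError
from tregdegron.simulate import DECOY_CONSENSUS, STAT_CONSENSUS


def test_module_assignment_partitions_genes():
    cfg = td.SimulationConfig(
        n_genes=100,
        module_sizes={"direct_activated": 5, "direct_repressed": 5,
                      "indirect": 10, "null": 80},
        n_state_marker_genes=5,
        n_mito_genes=3,
    )
    truth = td.make_ground_truth(cfg)
    counts = truth.gene_module.value_counts().to_dict()
    assert counts == {"null": 80, "indirect": 10,
                      "direct_activated": 5, "direct_repressed": 5}
    assert len(truth.gene_ids) == len(set(truth.gene_ids)) == 100


def test_oversized_modules_rejected():
    with pytest.raises(ConfigError):
        td.SimulationConfig(
            n_genes=10,
            module_sizes={"direct_activated": 6, "direct_repressed": 6,
                          "indirect": 0, "null": 0},
        )


def test_effect_ordering_enforced():
    with pytest.raises(ConfigError):
        td.SimulationConfig(effect_day3=4.0, effect_day7=2.0)
    with pytest.raises(ConfigError):
        td.SimulationConfig(effect_day3=0.5, effect_day7=2.0)


def test_ground_truth_deterministic(small_config):
    a = td.make_ground_truth(small_config)
    b = td.make_ground_truth(small_config)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    pd.testing.assert_series_equal(a.gene_module, b.gene_module)
    pd.testing.assert_frame_equal(a.log2fc_by_day, b.log2fc_by_day)


def test_planted_sign_convention():
    """Degradation removes an activator: direct_activated genes go down."""
    cfg = td.SimulationConfig(effect_day3=2.0, effect_day7=2.0)
    truth = td.make_ground_truth(cfg)
    act = truth.module_genes("direct_activated")[0]
    rep = truth.module_genes("direct_repressed")[0]
    nul = truth.module_genes("null")[0]
    assert truth.true_log2fc(act, "resting", 7) == -1.0
    assert truth.true_log2fc(rep, "resting", 7) == 1.0
    for day in (0, 3, 7):
        assert truth.true_log2fc(nul, "resting", day) == 0.0


def test_indirect_effect_only_day7_at_half_magnitude():
    cfg = td.SimulationConfig(effect_day7=4.0)
    truth = td.make_ground_truth(cfg)
    ind = truth.module_genes("indirect")
    day7 = truth.log2fc_by_day.loc[ind, 7]
    assert (truth.log2fc_by_day.loc[ind, 3] == 0).all()
    assert np.allclose(np.abs(day7), 1.0)  # half of log2(4) in either direction
    assert (day7 > 0).any() and (day7 < 0).any()


def test_counts_deterministic_and_conserved(small_config, small_truth, small_dataset):
    counts, cells = small_dataset
    counts2, cells2 = td.simulate_cells(small_truth, small_config)
    assert counts == counts2
    pd.testing.assert_frame_equal(cells, cells2)
    assert counts.n_cells == len(cells)


def test_null_genes_unbiased_at_day_zero():
    """With all multipliers 1 (day 0) null genes show no genotype fold change."""
    cfg = td.SimulationConfig(days=(0,), n_cells_per_group=250, seed=8)
    truth = td.make_ground_truth(cfg)
    counts, cells = td.simulate_cells(truth, cfg)
    assert counts.n_cells >= 2000
    dense = counts.to_dense().astype(float)
    degr = (cells["genotype"] == "degrader").to_numpy()
    cpm_a = dense[~degr] / dense[~degr].sum(axis=1, keepdims=True)
    cpm_b = dense[degr] / dense[degr].sum(axis=1, keepdims=True)
    lfc = np.log2(cpm_b.mean(axis=0) + 1e-9) - np.log2(cpm_a.mean(axis=0) + 1e-9)
    null_idx = counts.gene_index(truth.module_genes("null"))
    assert abs(float(lfc[null_idx].mean())) < 0.05


def test_proliferating_cells_amplify_direct_effect():
    cfg = td.SimulationConfig(
        days=(7,), n_cells_per_group=150, effect_day3=2.0, effect_day7=2.0,
        proliferation_amplification=2.0,
        frac_proliferating_given_state={"resting": 0.4, "activated": 0.4},
        seed=4,
    )
    truth = td.make_ground_truth(cfg)
    counts, cells = td.simulate_cells(truth, cfg)
    dense = counts.to_dense().astype(float)
    frac = dense / dense.sum(axis=1, keepdims=True)
    direct = counts.gene_index(truth.module_genes("direct_repressed"))
    degr = (cells["genotype"] == "degrader").to_numpy()
    prol = cells["proliferating"].to_numpy()
    ctrl = frac[~degr][:, direct].mean()
    fc_prolif = frac[degr & prol][:, direct].mean() / ctrl
    fc_quiet = frac[degr & ~prol][:, direct].mean() / ctrl
    assert fc_prolif > fc_quiet > 1.0


def test_zero_cells_gives_consistent_empty_outputs():
    cfg = td.SimulationConfig(n_cells_per_group=0)
    truth = td.make_ground_truth(cfg)
    counts, cells = td.simulate_cells(truth, cfg)
    assert counts.shape == (0, cfg.n_genes)
    assert len(cells) == 0


# ---------------------------------------------------------------------------
# hashtags
# ---------------------------------------------------------------------------

def _droplet_meta(n, n_samples=4):
    return pd.DataFrame(
        {"cell_id": [f"d{i}" for i in range(n)],
         "sample": [f"s{i % n_samples}" for i in range(n)]}
    )


def test_hto_no_doublets_when_rate_zero():
    cfg = td.SimulationConfig(doublet_rate=0.0, seed=2)
    _, truth = td.simulate_hto(_droplet_meta(500), cfg)
    assert not (truth["true_call"] == "doublet").any()


def test_hto_zero_background_means_zero_offtarget_counts():
    cfg = td.SimulationConfig(hto_background_mean=0.0, seed=2)
    hto, truth = td.simulate_hto(_droplet_meta(300), cfg)
    for i, planted in enumerate(truth["planted_tags"]):
        positives = set(planted.split(",")) - {""}
        off = [t for t in hto.columns if t not in positives]
        assert (hto.iloc[i][off] == 0).all()


def test_hto_singlet_fraction_within_binomial_ci():
    cfg = td.SimulationConfig(seed=13)
    _, truth = td.simulate_hto(_droplet_meta(5000), cfg)
    n_singlet = int((~truth["true_call"].isin(["doublet", "negative"])).sum())
    p = 1 - cfg.doublet_rate - cfg.negative_rate
    lo, hi = stats.binom.ppf([0.005, 0.995], 5000, p)
    assert lo <= n_singlet <= hi


def test_hto_rejects_impossible_rates():
    cfg = td.SimulationConfig()
    object.__setattr__(cfg, "doublet_rate", 0.7)
    object.__setattr__(cfg, "negative_rate", 0.5)
    with pytest.raises(ConfigError):
        td.simulate_hto(_droplet_meta(10), cfg)


# ---------------------------------------------------------------------------
# regulatory layer
# ---------------------------------------------------------------------------

def test_degenerate_bound_probabilities(small_truth, small_config):
    cfg = small_config.replace(foxp3_bound_frac_direct=1.0, foxp3_bound_frac_other=0.0)
    reg = td.simulate_regulatory_annotation(small_truth, cfg)
    direct = set(small_truth.module_genes("direct_activated", "direct_repressed"))
    near_direct = reg.peaks["source_gene"].isin(direct)
    assert reg.peaks.loc[near_direct, "foxp3_flag"].all()
    assert not reg.peaks.loc[~near_direct, "foxp3_flag"].any()


def test_intervals_half_open_and_bound_subset_of_open(regulatory_truth):
    peaks = regulatory_truth.peaks
    assert (peaks["start"] < peaks["end"]).all()
    assert (peaks["start"] >= 0).all()
    assert peaks.loc[peaks["foxp3_flag"], "atac_flag"].all()
    genes = regulatory_truth.genes
    assert (genes["start"] < genes["end"]).all()
    # gene loci do not overlap
    by_pos = genes.sort_values("start")
    assert (by_pos["start"].to_numpy()[1:] >= by_pos["end"].to_numpy()[:-1]).all()


def test_planted_motifs_recoverable_by_string_scan(regulatory_truth):
    """Brute-force string search over the FASTA finds every recorded plant."""
    consensus = {"STAT_like": STAT_CONSENSUS, "bZIP_decoy": DECOY_CONSENSUS}
    for peak_id, plants in regulatory_truth.planted_motifs.items():
        seq = regulatory_truth.sequences[peak_id]
        for motif, offset, strand in plants:
            word = consensus[motif]
            assert strand == "+"
            found = [i for i in range(len(seq) - len(word) + 1)
                     if seq[i:i + len(word)] == word]
            assert offset in found


# ---------------------------------------------------------------------------
# suppression wells
# ---------------------------------------------------------------------------

def test_suppression_wells_reflect_planted_strength():
    cfg = td.SimulationConfig(seed=6, n_wells=20)
    wells = td.simulate_suppression_assay(cfg)
    control = wells.loc[wells["condition"] == "noTreg", "divided_fraction"].mean()
    top = wells[wells["treg_ratio"] == 1.0]
    observed = td.percent_suppression(control, top["divided_fraction"].mean())
    assert observed == pytest.approx(100 * cfg.suppression_max, abs=5)


def test_suppression_null_and_full_limits():
    cfg = td.SimulationConfig(seed=6, suppression_max=0.0, n_wells=30)
    wells = td.simulate_suppression_assay(cfg)
    curve = td.suppression_curve(wells)
    treg = curve[curve["condition"] != "noTreg"]
    assert np.abs(treg["percent_suppression"]).max() < 5

    cfg_full = td.SimulationConfig(seed=6, suppression_max=1.0)
    wells = td.simulate_suppression_assay(cfg_full)
    full = wells[wells["treg_ratio"] == 1.0]
    assert (full["divided_fraction"] == 0).all()
    control = wells.loc[wells["condition"] == "noTreg", "divided_fraction"].mean()
    assert td.percent_suppression(control, 0.0) == 100.0
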