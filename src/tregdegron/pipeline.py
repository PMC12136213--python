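"""End-to-end orchestration: demo dataset generation and the staged run.

``make_demo`` writes a self-contained synthetic dataset emulating the
study design (two genotypes x days 0/3/7 x four replicates, hashed in one
pool per time point) plus a matching pipeline config. ``run_pipeline``
executes qc -> demux -> scoring/classification -> pseudo-bulk DE ->
grouping -> strata -> regulatory enrichment -> assay summaries and writes
a manifest with the config hash, seeds, per-stage row counts and output
digests; rerunning the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io
from .assays import suppression_curve
from .config import ConfigError, QCThresholds, SimulationConfig, qc_profile
from .containers import CountMatrix
from .enrichment import (
    aggregate_signal_at_peaks,
    assign_peaks_to_genes,
    enrichment_test,
    group_bound_fraction,
)
from .motifs import motif_enrichment_table
from .pseudobulk import (
    aggregate_pseudobulk,
    classify_gene_groups,
    differential_expression,
    stratify_by_pvalue,
)
from .qc import filter_cells, filter_genes, kmeans_demux, normalize_counts
from .scoring import (
    build_metacells,
    classify_states,
    metacell_dose_correlation,
    metacell_score,
    signature_score,
)
from .simulate import (
    GroundTruth,
    make_ground_truth,
    simulate_cells,
    simulate_hto,
    simulate_regulatory_annotation,
    simulate_suppression_assay,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Structured configuration of a full pipeline run."""

    data_dir: str
    out_dir: str
    qc_profile: str = "flex"
    min_umi: int = 1000
    min_genes: int = 1000
    days: List[int] = field(default_factory=lambda: [0, 3, 7])
    de_days: List[int] = field(default_factory=lambda: [3, 7])
    q_threshold: float = 0.05
    lfc_threshold: float = 0.0
    score_n_bins: int = 25
    score_ctrl_size: int = 50
    threshold_rest: float = 0.0
    threshold_act: float = 0.0
    metacell_size: int = 20
    window_kb: float = 50.0
    n_perm: int = 999
    anchor_gene: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def validate(self) -> None:
        data = Path(self.data_dir)
        required = ["matrix.mtx", "barcodes.tsv", "features.tsv", "pools.tsv",
                    "mito_genes.txt", "signature_resting.txt",
                    "signature_activated.txt", "genes.tsv", "peaks.bed",
                    "peaks.fasta", "pwms.txt", "suppression_wells.tsv"]
        required += [f"hto_d{day}.tsv" for day in self.days]
        required += [f"hto_d{day}_tags.tsv" for day in self.days]
        missing = [f for f in required if not (data / f).exists()]
        if missing:
            raise ConfigError(f"missing input files in {data}: {missing}")
        qc_profile(self.qc_profile)


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def demo_simulation_config(seed: int = 0, n_genes: int = 600) -> SimulationConfig:
    """Simulation config scaled for a fast end-to-end demo run."""
    n_null = n_genes - 60
    return SimulationConfig(
        n_genes=n_genes,
        n_cells_per_group=40,
        module_sizes={
            "direct_activated": 20,
            "direct_repressed": 20,
            "indirect": 20,
            "null": n_null,
        },
        n_hto_tags=8,  # 2 genotypes x 4 replicates hashed per time-point pool
        seed=seed,
    )


def make_demo(seed: int, out_dir, n_genes: int = 600) -> PipelineConfig:
    """Write a self-contained synthetic dataset plus a matching config."""
    out = Path(out_dir)
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)

    sim = demo_simulation_config(seed=seed, n_genes=n_genes)
    truth = make_ground_truth(sim)
    counts, cells = simulate_cells(truth, sim)

    io.write_count_matrix(counts, data / "matrix.mtx", data / "barcodes.tsv",
                          data / "features.tsv")
    cells[["cell_id", "day"]].to_csv(data / "pools.tsv", sep="\t", index=False)

    hto_truths = []
    for day in sim.days:
        pool = cells[cells["day"] == day]
        hto, hto_truth = simulate_hto(pool, sim.replace(seed=seed + 1000 + day))
        hto.to_csv(data / f"hto_d{day}.tsv", sep="\t")
        samples = sorted(pool["sample"].unique())
        tag_map = pd.DataFrame(
            {"tag": [f"HTO{i + 1}" for i in range(len(samples))], "sample": samples}
        )
        tag_map.to_csv(data / f"hto_d{day}_tags.tsv", sep="\t", index=False)
        hto_truths.append(hto_truth)

    reg = simulate_regulatory_annotation(truth, sim)
    io.write_gene_annotation(reg.genes, data / "genes.tsv")
    io.write_peaks(reg.peaks[io.PEAK_COLUMNS], data / "peaks.bed")
    io.write_fasta(reg.sequences, data / "peaks.fasta")
    io.write_pwms(reg.pwms, data / "pwms.txt")

    io.write_signature(truth.state_markers["resting"], data / "signature_resting.txt")
    io.write_signature(truth.state_markers["activated"], data / "signature_activated.txt")
    io.write_signature(truth.mito_genes, data / "mito_genes.txt")

    wells = simulate_suppression_assay(sim)
    io.write_table(wells, data / "suppression_wells.tsv")

    gt = truth.to_json_dict()
    gt["hto_truth"] = pd.concat(hto_truths, ignore_index=True).to_dict(orient="list")
    io.write_json(gt, data / "ground_truth.json")

    config = PipelineConfig(
        data_dir=str(data),
        out_dir=str(out / "run"),
        min_genes=200,  # toy genome has far fewer genes than a transcriptome
        anchor_gene=truth.anchor_gene,
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config


# ---------------------------------------------------------------------------
# pipeline run
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _parse_sample(call: str) -> Optional[Dict[str, object]]:
    # sample labels look like "<genotype>_d<day>_r<rep>"
    parts = call.rsplit("_", 2)
    if len(parts) != 3 or not parts[1].startswith("d") or not parts[2].startswith("r"):
        return None
    try:
        return {
            "genotype": parts[0],
            "day": int(parts[1][1:]),
            "replicate": int(parts[2][1:]),
        }
    except ValueError:
        return None


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage and return the manifest dictionary."""
    config.validate()
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_row = {}
    t0 = time.time()

    def stage(name):
        logger.info("[%7.2fs] stage %s", time.time() - t0, name)

    # ---- qc ---------------------------------------------------------------
    stage("qc")
    raw = io.read_count_matrix(data / "matrix.mtx", data / "barcodes.tsv",
                               data / "features.tsv")
    mito = io.read_signature(data / "mito_genes.txt")
    thresholds = qc_profile(config.qc_profile)
    thresholds = dataclasses.replace(
        thresholds, min_umi=config.min_umi, min_genes=config.min_genes
    )
    filtered, removal = filter_cells(raw, mito, thresholds)
    filtered = filter_genes(filtered, thresholds)
    io.write_table(removal, out / "qc_removed_cells.tsv")
    counts_row["qc_cells_in"] = raw.n_cells
    counts_row["qc_cells_out"] = filtered.n_cells
    counts_row["qc_genes_out"] = filtered.n_genes

    # ---- demux ------------------------------------------------------------
    stage("demux")
    pools = io.read_table(data / "pools.tsv", dtype={"cell_id": str})
    calls = []
    for day in config.days:
        hto = pd.read_csv(data / f"hto_d{day}.tsv", sep="\t", index_col="cell_id")
        tag_map = io.read_table(data / f"hto_d{day}_tags.tsv")
        call = kmeans_demux(hto, dict(zip(tag_map["tag"], tag_map["sample"])))
        call["day"] = day
        calls.append(call)
    demux = pd.concat(calls, ignore_index=True)
    io.write_table(demux.drop(columns="day"), out / "demux_calls.tsv")

    meta_rows = []
    for row in demux.itertuples(index=False):
        parsed = _parse_sample(row.call)
        if parsed is None:
            continue  # doublet or negative
        meta_rows.append({"cell_id": row.cell_id, "sample": row.call, **parsed})
    meta = pd.DataFrame(meta_rows)
    meta = meta[meta["cell_id"].isin(filtered.cell_ids)]
    filtered = filtered.subset_cells(
        np.isin(np.array(filtered.cell_ids), meta["cell_id"].to_numpy())
    )
    counts_row["demux_singlets"] = len(meta)

    # ---- scoring / classification -----------------------------------------
    stage("score")
    norm = normalize_counts(filtered)
    sig_rest = io.read_signature(data / "signature_resting.txt")
    sig_act = io.read_signature(data / "signature_activated.txt")
    score_rest = signature_score(norm, sig_rest, config.score_n_bins,
                                 config.score_ctrl_size, seed=config.seed + 1)
    score_act = signature_score(norm, sig_act, config.score_n_bins,
                                config.score_ctrl_size, seed=config.seed + 2)
    states = classify_states(score_rest, score_act,
                             (config.threshold_rest, config.threshold_act))
    meta = meta.set_index("cell_id")
    meta["score_resting"] = score_rest
    meta["score_activated"] = score_act
    meta["state"] = states
    meta = meta.reset_index()
    io.write_table(meta, out / "cell_states.tsv")
    counts_row["cells_classified"] = int((meta["state"] != "unassigned").sum())

    # ---- pseudo-bulk DE ----------------------------------------------------
    stage("de")
    de_tables: Dict[str, Dict[int, pd.DataFrame]] = {}
    for state in ("resting", "activated"):
        de_tables[state] = {}
        for day in config.de_days:
            sel = meta[(meta["state"] == state) & (meta["day"].isin([0, day]))]
            # day 0 is untreated baseline for both genotypes; the contrast uses
            # treated cells only, so restrict to the target day
            sel = sel[sel["day"] == day]
            if sel.empty:
                continue
            sub = filtered.subset_cells(
                np.isin(np.array(filtered.cell_ids), sel["cell_id"].to_numpy())
            )
            pb = aggregate_pseudobulk(sub, sel, keys=("replicate", "genotype"))
            de = differential_expression(pb)
            de_tables[state][day] = de
            io.write_de_table(de, out / f"de_{state}_day{day}.tsv")
            counts_row[f"de_{state}_day{day}_genes"] = len(de)

    # ---- gene groups and strata -------------------------------------------
    stage("groups")
    day7 = {s: t[7] for s, t in de_tables.items() if 7 in t}
    groups = classify_gene_groups(day7, config.q_threshold, config.lfc_threshold)
    io.write_json(groups.to_dict(), out / "gene_groups.json")
    if "resting" in day7:
        strata = stratify_by_pvalue(day7["resting"])
        io.write_table(strata, out / "strata_resting_day7.tsv")
        counts_row["strata_rows"] = len(strata)

    # ---- regulatory enrichment --------------------------------------------
    stage("enrich")
    genes_tab = io.read_gene_annotation(data / "genes.tsv")
    peaks = io.read_peaks(data / "peaks.bed")
    pgmap = assign_peaks_to_genes(peaks, genes_tab, config.window_kb)
    group_sets = {k: v for k, v in groups.to_dict().items() if v}
    enr_rows = []
    if group_sets:
        fractions = group_bound_fraction(pgmap, group_sets)
        all_genes = list(genes_tab["gene_id"])
        for name, ge in fractions.items():
            focal = group_sets[name]
            background = [g for g in all_genes if g not in set(focal)]
            p, obs, _ = enrichment_test(pgmap, focal, background,
                                        n_perm=config.n_perm, seed=config.seed + 7)
            enr_rows.append((name, ge.n_genes, ge.total_atac, ge.total_foxp3,
                             ge.bound_fraction, p))
    enr = pd.DataFrame(enr_rows, columns=["group", "n_genes", "n_atac", "n_foxp3",
                                          "bound_fraction", "perm_p"])
    io.write_table(enr, out / "binding_enrichment.tsv")

    signal_frames = []
    for signal in ("h3k27ac", "h3k27me3"):
        tab = aggregate_signal_at_peaks(pgmap, peaks, group_sets, signal=signal)
        tab.insert(0, "signal", signal)
        signal_frames.append(tab)
    if signal_frames:
        io.write_table(pd.concat(signal_frames, ignore_index=True),
                       out / "histone_signals.tsv")

    sequences = io.read_fasta(data / "peaks.fasta")
    pwms = io.read_pwms(data / "pwms.txt")
    bound = peaks[peaks["foxp3_flag"]]
    down_genes = set(groups.resting_TIR1_down)
    fg_peaks = sorted({
        p for g in down_genes for p in pgmap.peaks_by_gene.get(g, [])
        if p in set(bound["peak_id"])
    })
    bg_peaks = sorted(set(bound["peak_id"]) - set(fg_peaks))
    if fg_peaks and bg_peaks:
        motif_tab = motif_enrichment_table(sequences, pwms, fg_peaks, bg_peaks)
        io.write_table(motif_tab, out / "motif_enrichment.tsv")
        counts_row["motifs_tested"] = len(motif_tab)

    # ---- meta-cell dose-response ------------------------------------------
    stage("metacell")
    mc_rows = []
    if config.anchor_gene and config.anchor_gene in norm.gene_ids:
        degr = meta[(meta["genotype"] != "control") & (meta["state"] != "unassigned")]
        sub = norm.subset_cells(
            np.isin(np.array(norm.cell_ids), degr["cell_id"].to_numpy())
        )
        strata_lab = pd.Series(
            (degr["sample"] + "|" + degr["state"]).to_numpy(),
            index=degr["cell_id"],
        ).reindex(sub.cell_ids)
        metacells = build_metacells(sub, strata_lab, config.metacell_size,
                                    seed=config.seed + 11)
        if len(metacells) >= 3:
            for name, sig in (("TIR1_down", groups.resting_TIR1_down),
                              ("TIR1_up", groups.resting_TIR1_up)):
                sig = [g for g in sig if g != config.anchor_gene and g in norm.gene_ids]
                if not sig:
                    continue
                scores = metacell_score(metacells, norm.gene_ids, sig)
                try:
                    r, p = metacell_dose_correlation(
                        metacells, norm.gene_ids, config.anchor_gene, scores
                    )
                except Exception as exc:  # zero-variance degenerate strata
                    logger.warning("meta-cell correlation for %s failed: %s", name, exc)
                    continue
                mc_rows.append((name, len(metacells), r, p))
    io.write_table(
        pd.DataFrame(mc_rows, columns=["signature", "n_metacells", "pearson_r", "p"]),
        out / "metacell_correlations.tsv",
    )

    # ---- assays ------------------------------------------------------------
    stage("assays")
    wells = io.read_table(data / "suppression_wells.tsv")
    io.write_table(suppression_curve(wells), out / "suppression_curve.tsv")

    # ---- manifest ----------------------------------------------------------
    stage("manifest")
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "pipeline_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_counts": counts_row,
        "outputs": {p.name: _digest(p) for p in outputs},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
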