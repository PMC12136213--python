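"""Configuration objects for the simulator, QC stage and pipeline.

All knobs that the analyses depend on are collected here so that a single
config (plus its seed) fully determines every output of the pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import math

MODULE_LABELS = ("direct_activated", "direct_repressed", "indirect", "null")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic degron experiment.

    The defaults emulate the study design: two genotypes (control vs.
    degrader) sampled at days 0/3/7 of ligand treatment with four biological
    replicates each, UMI counts drawn negative-binomially over resting /
    activated / proliferating Treg states, and a small direct-target gene
    module whose response grows from day 3 to day 7 and is amplified in
    proliferating cells.
    """

    n_genes: int = 2000
    n_cells_per_group: int = 50  # cells per genotype x day x replicate
    genotypes: Tuple[str, str] = ("control", "degrader")
    days: Tuple[int, ...] = (0, 3, 7)
    n_replicates_per_genotype: int = 4
    frac_activated: float = 0.4
    frac_proliferating_given_state: Dict[str, float] = field(
        default_factory=lambda: {"resting": 0.05, "activated": 0.30}
    )
    module_sizes: Dict[str, int] = field(
        default_factory=lambda: {
            "direct_activated": 50,
            "direct_repressed": 50,
            "indirect": 100,
            "null": 1800,
        }
    )
    effect_day3: float = 2.0
    effect_day7: float = 4.0
    proliferation_amplification: float = 2.0
    libsize_mean: float = 5000.0
    libsize_sigma: float = 0.3
    nb_dispersion: float = 0.05
    baseline_sigma: float = 1.0
    mito_gene_frac: float = 0.02
    n_mito_genes: int = 10

    # cell-state marker modules used by the signature-scoring stage
    n_state_marker_genes: int = 30
    state_marker_fold: float = 3.0

    # hashtag (HTO) layer
    n_hto_tags: int = 4
    hto_positive_mean: float = 150.0
    hto_background_mean: float = 3.0
    doublet_rate: float = 0.05
    negative_rate: float = 0.01

    # regulatory annotation layer
    foxp3_bound_frac_direct: float = 0.6
    foxp3_bound_frac_other: float = 0.2
    gene_locus_halfwidth: int = 50_000
    peak_region_halfwidth: int = 40_000
    peak_width: int = 300
    mean_extra_peaks_per_gene: float = 4.0
    peak_seq_len: int = 300
    motif_plant_prob_target: float = 0.8
    motif_plant_prob_background: float = 0.05
    histone_means: Dict[str, Tuple[float, float]] = field(
        # module -> (H3K27ac mean, H3K27me3 mean)
        default_factory=lambda: {
            "direct_activated": (8.0, 1.0),
            "direct_repressed": (1.0, 8.0),
            "indirect": (3.0, 3.0),
            "null": (3.0, 3.0),
        }
    )

    # suppression assay layer
    treg_ratios: Tuple[float, ...] = (1.0, 0.5, 0.25, 0.125)
    suppression_max: float = 0.75
    control_divided_mean: float = 0.8
    n_wells: int = 3
    well_concentration: float = 200.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be non-negative")
        unknown = set(self.module_sizes) - set(MODULE_LABELS)
        if unknown:
            raise ConfigError(f"unknown gene modules: {sorted(unknown)}")
        if any(v < 0 for v in self.module_sizes.values()):
            raise ConfigError("module sizes must be non-negative")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise ConfigError(
                f"module sizes sum to {sum(self.module_sizes.values())} "
                f"> n_genes={self.n_genes}"
            )
        if self.effect_day3 <= 0 or self.effect_day7 <= 0:
            raise ConfigError("effect multipliers must be positive")
        l3, l7 = math.log(self.effect_day3), math.log(self.effect_day7)
        if l3 * l7 < 0:
            raise ConfigError("effect_day3 and effect_day7 must lie on the same side of 1")
        if abs(l7) < abs(l3):
            raise ConfigError(
                "the day-7 effect must be at least as large as the day-3 effect "
                "(time-dependent augmentation)"
            )
        if self.proliferation_amplification < 1:
            raise ConfigError("proliferation_amplification must be >= 1")
        for name in ("frac_activated", "mito_gene_frac", "doublet_rate",
                     "negative_rate", "foxp3_bound_frac_direct",
                     "foxp3_bound_frac_other", "motif_plant_prob_target",
                     "motif_plant_prob_background", "suppression_max",
                     "control_divided_mean"):
            _check_proportion(name, getattr(self, name))
        for state, frac in self.frac_proliferating_given_state.items():
            _check_proportion(f"frac_proliferating_given_state[{state}]", frac)
        if self.doublet_rate + self.negative_rate > 1:
            raise ConfigError("doublet_rate + negative_rate must not exceed 1")
        if self.n_hto_tags < 2:
            raise ConfigError("n_hto_tags must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.gene_locus_halfwidth <= 0 or self.peak_width <= 0:
            raise ConfigError("genomic window widths must be positive")
        if not (0 <= int(self.seed) < 2**31):
            raise ConfigError("seed must be a non-negative 31-bit integer")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("genotypes", "days", "treg_ratios"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "histone_means" in d:
            d["histone_means"] = {k: tuple(v) for k, v in d["histone_means"].items()}
        return cls(**d)


@dataclass
class QCThresholds:
    """Cell/gene filter thresholds.

    Boundary semantics follow the stated filters exactly: cells with *fewer
    than* ``min_umi`` UMIs or *fewer than* ``min_genes`` detected genes, or
    *more than* ``max_mito_frac`` mitochondrial counts, are removed — a cell
    sitting exactly on a threshold is retained. Genes expressed in *more
    than* ``min_cells_per_gene`` cells are retained.
    """

    min_umi: int = 1000
    min_genes: int = 1000
    max_mito_frac: float = 0.05
    min_cells_per_gene: int = 5

    def __post_init__(self) -> None:
        if min(self.min_umi, self.min_genes, self.min_cells_per_gene) < 0:
            raise ConfigError("QC thresholds must be non-negative")
        _check_proportion("max_mito_frac", self.max_mito_frac)


#: QC profiles: "flex" is the fixed-cell tumour-experiment profile (5% mito),
#: "steady_state" the fresh-cell profile (20% mito).
QC_PROFILES: Dict[str, QCThresholds] = {
    "flex": QCThresholds(max_mito_frac=0.05),
    "steady_state": QCThresholds(max_mito_frac=0.20),
}


def qc_profile(name: str) -> QCThresholds:
    try:
        return dataclasses.replace(QC_PROFILES[name])
    except KeyError:
        raise ConfigError(
            f"unknown QC profile {name!r}; choose from {sorted(QC_PROFILES)}"
        ) from None
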