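"""Configuration dataclasses for the synthetic generator and the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from caflineage.errors import ConfigError

#: Cell types generated by the simulator.  "fibroblast" cells carry the CAF
#: subtype structure; "epithelial" cells from tumor tissue play the role of
#: cancer cells.
CELL_TYPES = ("fibroblast", "epithelial", "endothelial", "tcell", "myeloid")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-sample single-cell + bulk generator.

    Defaults describe the study conditions the downstream analysis assumes:
    three discovery samples sharing six CAF subtypes, one of which (the
    "lineage" subtype, ~30% of CAFs) sits at the terminal end of a planted
    differentiation axis and exclusively expresses a marker gene (a GJB2
    analog) together with a collagen program.
    """

    n_samples: int = 3
    n_genes: int = 1500
    cells_per_sample: int = 1500
    cell_type_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "fibroblast": 0.40,
            "epithelial": 0.25,
            "endothelial": 0.13,
            "tcell": 0.13,
            "myeloid": 0.09,
        }
    )
    n_caf_subtypes: int = 6
    lineage_subtype_index: int = 5
    #: fraction of CAFs belonging to the lineage subtype (others split evenly)
    lineage_caf_fraction: float = 0.30
    #: fraction of fibroblasts sampled from normal tissue (these are the NFs)
    nf_fraction: float = 1 / 3
    marker_gene_id: str = "GJB2"
    #: genes per planted program (collagen/lineage program uses "lineage")
    program_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "fib_common": 20,
            "fib_early": 60,
            "fib_late": 60,
            "caf_subtype": 25,
            "lineage": 40,
            "cell_type": 40,
        }
    )
    #: mean elevation of program genes over baseline, in log2 units
    program_effect: float = 3.0
    #: slope of the (1 + a*t) pseudotime modulation of the lineage program
    pseudotime_slope: float = 2.0
    nb_dispersion: float = 0.1
    mito_gene_count: int = 13
    qc_violation_fractions: dict[str, float] = field(
        default_factory=lambda: {"low_genes": 0.01, "low_umi": 0.01, "high_mito": 0.01}
    )
    lr_pairs_planted: list[tuple[str, str, str, str]] = field(
        default_factory=lambda: [
            ("PDGFB", "PDGFRB", "endothelial", "lineage_caf"),
            ("DLL4", "NOTCH3", "endothelial", "lineage_caf"),
            ("CXCL12", "CXCR4", "endothelial", "lineage_caf"),
        ]
    )
    #: decoy ligand-receptor pairs per planted pair
    lr_decoy_multiplier: int = 5
    mean_library_size: float = 6000.0
    library_size_sigma: float = 0.25
    bulk_n: int = 500
    hazard_beta: float = 1.0
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        fr = self.cell_type_fractions
        if set(fr) != set(CELL_TYPES):
            raise ConfigError(f"cell_type_fractions must have keys {CELL_TYPES}")
        if abs(sum(fr.values()) - 1.0) > 1e-8:
            raise ConfigError("cell_type_fractions must sum to 1")
        if any(not 0 <= v <= 1 for v in fr.values()):
            raise ConfigError("cell type fractions must lie in [0, 1]")
        if not 0 <= self.lineage_subtype_index < self.n_caf_subtypes:
            raise ConfigError("lineage_subtype_index must be < n_caf_subtypes")
        for name, v in self.qc_violation_fractions.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"qc_violation_fraction[{name}] outside [0, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if not 0 < self.lineage_caf_fraction < 1:
            raise ConfigError("lineage_caf_fraction must lie in (0, 1)")
        n_program_genes = (
            self.program_sizes["fib_common"]
            + self.program_sizes["fib_early"]
            + self.program_sizes["fib_late"]
            + self.program_sizes["caf_subtype"] * (self.n_caf_subtypes - 1)
            + self.program_sizes["lineage"]
            + self.program_sizes["cell_type"] * (len(CELL_TYPES) - 1)
            + self.mito_gene_count
            + 20  # named marker/LR/housekeeping slots
        )
        if self.n_genes < n_program_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} smaller than the {n_program_genes} genes "
                "required by the configured program sizes"
            )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
        d = dict(d)
        if "lr_pairs_planted" in d:
            d["lr_pairs_planted"] = [tuple(p) for p in d["lr_pairs_planted"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class QCParams:
    min_genes: int = 200
    max_genes: int = 6000
    min_umi: int = 1000
    max_mito: float = 0.20
    mito_prefix: str = "MT-"
    scale_factor: float = 10_000.0


@dataclass
class VariableGeneParams:
    min_mean: float = 0.0125
    max_mean: float = 3.0
    min_dispersion: float = 0.5
    n_top: int = 1000
    n_bins: int = 20


@dataclass
class ClusterParams:
    n_pcs: int = 20
    k_neighbors: int = 20
    resolution: float = 0.8
    caf_resolution: float = 0.6
    snn_prune: float = 1 / 15
    clip: float = 10.0


@dataclass
class MarkerParams:
    top_n: int = 75
    min_positive_fraction: float = 0.1
    pseudocount: float = 1e-9


@dataclass
class LineageParams:
    ordering_alpha: float = 0.001
    caf_min_frac: float = 0.25
    nf_max_frac: float = 0.05
    rho_min: float = 0.3


@dataclass
class CrosstalkParams:
    n_perm: int = 999
    alpha: float = 0.05
    min_group_size: int = 10


@dataclass
class EnrichmentParams:
    weight: float = 1.0
    n_perm: int = 999
    name_filter: tuple[str, ...] = ("MESEN", "FIBRO")


@dataclass
class ClinicalParams:
    split_rule: str = "median"
    adjusters: tuple[str, ...] = ("stage", "age", "sex")


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    qc: QCParams = field(default_factory=QCParams)
    variable_genes: VariableGeneParams = field(default_factory=VariableGeneParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    markers: MarkerParams = field(default_factory=MarkerParams)
    lineage: LineageParams = field(default_factory=LineageParams)
    crosstalk: CrosstalkParams = field(default_factory=CrosstalkParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    seed: int = 0

    _SECTIONS = {
        "synthetic": SyntheticConfig,
        "qc": QCParams,
        "variable_genes": VariableGeneParams,
        "clustering": ClusterParams,
        "markers": MarkerParams,
        "lineage": LineageParams,
        "crosstalk": CrosstalkParams,
        "enrichment": EnrichmentParams,
        "clinical": ClinicalParams,
    }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        unknown = set(d) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        kwargs: dict[str, Any] = {"seed": int(d.get("seed", 0))}
        for name, klass in cls._SECTIONS.items():
            block = d.get(name, {})
            if name == "synthetic":
                block = dict(block)
                block.setdefault("seed", kwargs["seed"])
                kwargs[name] = SyntheticConfig.from_dict(block)
                continue
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - known
            if unknown:
                raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
            kwargs[name] = klass(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def snapshot(self, path: str | Path) -> None:
        """Write the resolved configuration next to a run's outputs."""
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
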