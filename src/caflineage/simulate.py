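"""Seeded synthetic multi-sample single-cell and bulk data generator.

The generator plants the structure the analysis is designed to recover:

* several discovery samples share the same gene programs (sample-specific
  library sizes and fresh counting noise), each containing fibroblasts,
  epithelial/cancer cells, endothelial cells, T cells and myeloid cells;
* fibroblasts carry a one-dimensional differentiation axis ``t in [0, 1]``
  with normal fibroblasts (NFs) at the origin and the CAF subtypes occupying
  successive bands; an "early fibroblast" program fades out along the axis
  (activity ``1 - t``) so the axis is geometrically recoverable;
* the terminal band belongs to the lineage subtype, which exclusively
  expresses a marker gene (a GJB2 analog) plus a collagen program, both
  modulated by ``1 + a*t`` so expression rises monotonically in pseudotime;
* endothelial cells over-express planted ligands whose receptors sit on the
  lineage subtype, on top of a decoy ligand-receptor background;
* low-quality cells violating each QC rule (too few detected genes, too few
  UMIs, high mitochondrial fraction) are planted and flagged;
* an independent bulk cohort carries a continuous latent signature whose
  hazard is log-linear with a configurable coefficient, a stage label whose
  odds of "high stage" increase with the signature, and independent
  exponential censoring calibrated to the requested censoring rate.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.special import expit

from caflineage.config import CELL_TYPES, SyntheticConfig
from caflineage.errors import ConfigError

# Named gene slots.  Program genes beyond these are generic "G####" ids.
FIB_MARKER_GENES = ["DCN", "COL3A1", "THY1"]
NF_COMMON_GENE = "VIM"  # expressed by essentially all fibroblasts, NF included
TYPE_ANCHOR_GENES = {
    "epithelial": "EPCAM",
    "endothelial": "PECAM1",
    "tcell": "CD3D",
    "myeloid": "LYZ",
}

_STAGE_CYCLE = ["Stage 1", "Stage 3", "Stage 2", "Stage 4", "LOW", "HIGH"]

# Relative-abundance weights (arbitrary units).  Baselines are lognormal with
# a heavy tail (a few housekeeping-like genes dominate the library), which
# keeps program genes in a realistic counts-per-10k range: a program weight of
# 2**program_effect over a total weight of ~10^4 gives a few counts per cell
# at the default library size, well inside the variable-gene mean cutoffs.
_BASE_SCALE = 2.0
_BASE_SIGMA = 1.3
_BASE_MU = 0.5
_BASE_PROGRAM = 0.02
_BASE_LINEAGE = 0.003
_BASE_MARKER = 0.001
_MARKER_BOOST = 3.0  # marker is the strongest lineage gene
_LIGAND_BOOST = 2.0
#: lineage program weight relative to the generic program weight; the
#: (1 + a*t) pseudotime modulation sits on top of this.  Kept low enough that
#: collagen genes drop out in ~10% of lineage cells — their pseudotime
#: correlation is attenuated relative to the high-expressed marker, which is
#: what puts the marker at the top of the correlation ranking.
_LINEAGE_WEIGHT = 0.2
_MITO_FRAC_NORMAL = 0.05
_MITO_VIOLATION_BOOST = 12.0


@dataclass
class GroundTruth:
    """Planted truth for one generated dataset.

    ``cells`` has one row per generated cell with columns sample, barcode,
    cell_type, subtype ('' for non-fibroblasts, 'NF', or 'CAF_<i>'),
    is_lineage, pseudotime (NaN outside fibroblasts) and qc_violation
    ('none', 'low_genes', 'low_umi' or 'high_mito').
    """

    cells: pd.DataFrame
    programs: dict[str, list[str]]
    marker_gene: str
    lineage_subtype: str
    signature_genes: list[str]
    lr_planted: list[tuple[str, str, str, str]]
    lr_decoys: list[tuple[str, str]]
    mito_genes: list[str]
    bulk_signature: pd.Series | None = None
    extras: dict = field(default_factory=dict)


class _Blueprint:
    """Gene layout and per-program weight rules shared by all samples."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        sizes = config.program_sizes
        ligands = [p[0] for p in config.lr_pairs_planted]
        receptors = [p[1] for p in config.lr_pairs_planted]
        named = (
            [config.marker_gene_id]
            + FIB_MARKER_GENES
            + [NF_COMMON_GENE]
            + ligands
            + receptors
            + list(TYPE_ANCHOR_GENES.values())
        )
        self.mito_genes = [f"MT-G{i + 1}" for i in range(config.mito_gene_count)]
        n_generic = config.n_genes - len(named) - len(self.mito_genes)
        if n_generic < 0:
            raise ConfigError("n_genes too small for the named gene slots")
        generic = [f"G{i:04d}" for i in range(n_generic)]
        self.genes = named + self.mito_genes + generic
        self.gene_index = {g: i for i, g in enumerate(self.genes)}

        pool = iter(generic)

        def take(n: int) -> list[str]:
            return [next(pool) for _ in range(n)]

        self.programs: dict[str, list[str]] = {
            "fib_common": FIB_MARKER_GENES + [NF_COMMON_GENE] + take(sizes["fib_common"]),
            "fib_early": take(sizes["fib_early"]),
            "fib_late": take(sizes["fib_late"]),
            "lineage": take(sizes["lineage"]) + receptors,
        }
        for s in range(config.n_caf_subtypes):
            if s == config.lineage_subtype_index:
                continue
            self.programs[f"subtype_{s}"] = take(sizes["caf_subtype"])
        for t in CELL_TYPES:
            if t == "fibroblast":
                continue
            prog = take(sizes["cell_type"]) + [TYPE_ANCHOR_GENES[t]]
            if t == "endothelial":
                prog += ligands
            self.programs[f"type_{t}"] = prog

        # Background genes carry baseline expression only; decoy LR pairs are
        # drawn from them so decoys have no planted group signal.
        in_program = {g for genes in self.programs.values() for g in genes}
        background = [g for g in generic if g not in in_program]
        n_decoy = config.lr_decoy_multiplier * len(config.lr_pairs_planted)
        decoy_genes = rng.choice(background, size=2 * n_decoy, replace=False)
        self.lr_decoys = [
            (str(decoy_genes[2 * i]), str(decoy_genes[2 * i + 1])) for i in range(n_decoy)
        ]
        self.background = background

        base = np.empty(config.n_genes)
        base[:] = _BASE_SCALE * rng.lognormal(_BASE_MU, _BASE_SIGMA, size=config.n_genes)
        for g in (
            self.programs["fib_common"]
            + self.programs["fib_early"]
            + self.programs["fib_late"]
        ):
            base[self.gene_index[g]] = 0.05
        for key, genes in self.programs.items():
            if key.startswith(("subtype_", "type_")):
                for g in genes:
                    base[self.gene_index[g]] = _BASE_PROGRAM
        for g in self.programs["lineage"]:
            base[self.gene_index[g]] = _BASE_LINEAGE
        base[self.gene_index[config.marker_gene_id]] = _BASE_MARKER
        # mitochondrial weight set so an ordinary cell sits near the normal
        # mito fraction; QC violators multiply this by _MITO_VIOLATION_BOOST
        mito_rows = [self.gene_index[g] for g in self.mito_genes]
        typical_program = 2.0 ** config.program_effect * (
            sizes["fib_common"] + sizes["caf_subtype"]
        )
        nonmito = base.sum() - base[mito_rows].sum() + typical_program
        base[mito_rows] = (
            _MITO_FRAC_NORMAL / (1 - _MITO_FRAC_NORMAL) * nonmito / len(mito_rows)
        )
        self.baseline = base
        self.effect = 2.0 ** config.program_effect

    def _program_rows(self, key: str) -> np.ndarray:
        return np.array([self.gene_index[g] for g in self.programs[key]])

    def weights(
        self,
        cell_type: np.ndarray,
        subtype: np.ndarray,
        t: np.ndarray,
    ) -> np.ndarray:
        """Expected relative-abundance weights, one row per cell."""
        cfg = self.config
        n = len(cell_type)
        w = np.tile(self.baseline, (n, 1))
        eff = self.effect
        fib = cell_type == "fibroblast"
        w[np.ix_(fib, self._program_rows("fib_common"))] += eff
        # two opposed gradient programs make the planted axis genuinely 1-D
        w[np.ix_(fib, self._program_rows("fib_early"))] += eff * (1.0 - t[fib])[:, None]
        w[np.ix_(fib, self._program_rows("fib_late"))] += eff * t[fib][:, None]
        for s in range(cfg.n_caf_subtypes):
            if s == cfg.lineage_subtype_index:
                continue
            sel = subtype == f"CAF_{s}"
            if sel.any():
                w[np.ix_(sel, self._program_rows(f"subtype_{s}"))] += eff
        lin = subtype == f"CAF_{cfg.lineage_subtype_index}"
        if lin.any():
            mod = (1.0 + cfg.pseudotime_slope * t[lin])[:, None]
            lw = _LINEAGE_WEIGHT * eff
            w[np.ix_(lin, self._program_rows("lineage"))] += lw * mod
            w[lin, self.gene_index[cfg.marker_gene_id]] += _MARKER_BOOST * lw * mod[:, 0]
        for ct in CELL_TYPES:
            if ct == "fibroblast":
                continue
            sel = cell_type == ct
            if sel.any():
                w[np.ix_(sel, self._program_rows(f"type_{ct}"))] += eff
        # extra boost for planted ligands so the cross-talk signal is strong
        endo = cell_type == "endothelial"
        if endo.any():
            for lig, _, _, _ in cfg.lr_pairs_planted:
                w[endo, self.gene_index[lig]] += (_LIGAND_BOOST - 1.0) * eff
        return w


def _exact_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so every class is represented."""
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def _axis_position(config: SyntheticConfig, subtype_idx: int) -> int:
    """Band index (1-based) of a CAF subtype on the planted axis.

    Non-lineage subtypes keep their index order; the lineage subtype always
    occupies the terminal band. NFs occupy band 0.
    """
    order = [s for s in range(config.n_caf_subtypes) if s != config.lineage_subtype_index]
    order.append(config.lineage_subtype_index)
    return order.index(subtype_idx) + 1


def _sample_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_multisample_sc(
    config: SyntheticConfig,
) -> tuple[list[ad.AnnData], GroundTruth]:
    """Generate the per-sample UMI count matrices and their planted truth.

    Returns one :class:`anndata.AnnData` per sample (cells x genes, raw
    counts in ``.X``; ``obs`` columns sample/tissue/stage) plus the
    :class:`GroundTruth` describing every planted feature.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bp = _Blueprint(config, rng)
    cfg = config
    K = cfg.n_caf_subtypes
    lineage_name = f"CAF_{cfg.lineage_subtype_index}"

    caf_fracs = {
        f"CAF_{s}": (
            cfg.lineage_caf_fraction
            if s == cfg.lineage_subtype_index
            else (1.0 - cfg.lineage_caf_fraction) / (K - 1)
        )
        for s in range(K)
    }

    adatas: list[ad.AnnData] = []
    truth_rows: list[pd.DataFrame] = []
    for si in range(cfg.n_samples):
        sample = f"S{si + 1}"
        stage = _STAGE_CYCLE[si % len(_STAGE_CYCLE)]
        n = cfg.cells_per_sample
        type_counts = _exact_counts(cfg.cell_type_fractions, n)
        cell_type = np.repeat(list(type_counts), list(type_counts.values()))
        rng.shuffle(cell_type)

        subtype = np.array([""] * n, dtype=object)
        tissue = np.empty(n, dtype=object)
        t = np.full(n, np.nan)
        fib_idx = np.flatnonzero(cell_type == "fibroblast")
        n_nf = int(round(cfg.nf_fraction * len(fib_idx)))
        nf_idx = fib_idx[:n_nf]
        caf_idx = fib_idx[n_nf:]
        subtype[nf_idx] = "NF"
        caf_counts = _exact_counts(caf_fracs, len(caf_idx))
        caf_labels = np.repeat(list(caf_counts), list(caf_counts.values()))
        rng.shuffle(caf_labels)
        subtype[caf_idx] = caf_labels

        # planted pseudotime: band 0 = NF, successive bands = subtypes
        t[nf_idx] = rng.uniform(0, 1 / (K + 1), size=len(nf_idx))
        for s in range(K):
            sel = np.flatnonzero(subtype == f"CAF_{s}")
            pos = _axis_position(cfg, s)
            t[sel] = rng.uniform(pos / (K + 1), (pos + 1) / (K + 1), size=len(sel))

        tissue[:] = np.where(rng.random(n) < 0.7, "tumor", "normal")
        tissue[nf_idx] = "normal"
        tissue[caf_idx] = np.where(rng.random(len(caf_idx)) < 0.9, "tumor", "border")
        # epithelial cells from tumor tissue are the "cancer" population
        epi_idx = np.flatnonzero(cell_type == "epithelial")
        tissue[epi_idx] = np.where(rng.random(len(epi_idx)) < 0.8, "tumor", "normal")

        # plant QC violations on disjoint random cells
        violation = np.array(["none"] * n, dtype=object)
        n_viol = {k: int(round(v * n)) for k, v in cfg.qc_violation_fractions.items()}
        viol_cells = rng.choice(n, size=sum(n_viol.values()), replace=False)
        offset = 0
        for rule, cnt in n_viol.items():
            violation[viol_cells[offset : offset + cnt]] = rule
            offset += cnt

        w = bp.weights(cell_type, subtype, t)
        lib = rng.lognormal(
            np.log(cfg.mean_library_size) - cfg.library_size_sigma**2 / 2,
            cfg.library_size_sigma,
            size=n,
        )
        mito_rows = np.array([bp.gene_index[g] for g in bp.mito_genes])
        low_genes = violation == "low_genes"
        if low_genes.any():
            non_mito = np.array([i for i in range(cfg.n_genes) if i not in set(mito_rows)])
            for ci in np.flatnonzero(low_genes):
                keep = rng.choice(non_mito, size=150, replace=False)
                row = np.zeros(cfg.n_genes)
                row[keep] = 1.0
                w[ci] = row
                lib[ci] = 3000.0
        lib[violation == "low_umi"] = 600.0
        high_mito = violation == "high_mito"
        if high_mito.any():
            w[np.ix_(high_mito, mito_rows)] *= _MITO_VIOLATION_BOOST

        mean = w / w.sum(axis=1, keepdims=True) * lib[:, None]
        counts = _sample_counts(rng, mean, cfg.nb_dispersion)

        barcodes = [f"{sample}:C{i:04d}" for i in range(n)]
        obs = pd.DataFrame(
            {"sample": sample, "tissue": tissue, "stage": stage},
            index=pd.Index(barcodes, name="barcode"),
        )
        adata = ad.AnnData(
            X=sp.csr_matrix(counts.astype(np.float64)),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(bp.genes, name="gene")),
        )
        adatas.append(adata)
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "barcode": barcodes,
                    "cell_type": cell_type,
                    "subtype": subtype,
                    "is_lineage": subtype == lineage_name,
                    "pseudotime": t,
                    "qc_violation": violation,
                }
            )
        )

    cells = pd.concat(truth_rows, ignore_index=True).set_index("barcode")
    truth = GroundTruth(
        cells=cells,
        programs={k: list(v) for k, v in bp.programs.items()},
        marker_gene=cfg.marker_gene_id,
        lineage_subtype=lineage_name,
        signature_genes=sorted(
            set(bp.programs["lineage"]) - {p[1] for p in cfg.lr_pairs_planted}
        )
        + [cfg.marker_gene_id],
        lr_planted=list(cfg.lr_pairs_planted),
        lr_decoys=list(bp.lr_decoys),
        mito_genes=list(bp.mito_genes),
    )
    return adatas, truth


def generate_reference_profiles(config: SyntheticConfig) -> pd.DataFrame:
    """Mean expression profile per cell type (genes x types).

    Profiles are the generating relative-abundance means: for fibroblasts a
    mixture over NF and the CAF subtypes at their band-center pseudotimes,
    weighted by the configured proportions; for the other types their program
    means. Each profile is scaled to sum to 10,000.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bp = _Blueprint(config, rng)
    K = config.n_caf_subtypes
    profiles = {}
    for ct in CELL_TYPES:
        if ct == "fibroblast":
            groups = ["NF"] + [f"CAF_{s}" for s in range(K)]
            ts = [0.5 / (K + 1)] + [
                (_axis_position(config, s) + 0.5) / (K + 1) for s in range(K)
            ]
            weights = [config.nf_fraction] + [
                (1 - config.nf_fraction)
                * (
                    config.lineage_caf_fraction
                    if s == config.lineage_subtype_index
                    else (1 - config.lineage_caf_fraction) / (K - 1)
                )
                for s in range(K)
            ]
            w = bp.weights(
                np.array(["fibroblast"] * len(groups)),
                np.array(groups, dtype=object),
                np.array(ts),
            )
            prof = np.average(w, axis=0, weights=weights)
        else:
            w = bp.weights(np.array([ct]), np.array([""], dtype=object), np.array([np.nan]))
            prof = w[0]
        profiles[ct] = prof / prof.sum() * 10_000.0
    return pd.DataFrame(profiles, index=pd.Index(bp.genes, name="gene"))


def generate_lr_database(config: SyntheticConfig) -> pd.DataFrame:
    """Ligand-receptor pair table: planted pairs plus decoy background pairs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bp = _Blueprint(config, rng)
    rows = [(lig, rec) for lig, rec, _, _ in config.lr_pairs_planted] + bp.lr_decoys
    return pd.DataFrame(rows, columns=["ligand", "receptor"]).drop_duplicates(
        ignore_index=True
    )


def generate_gene_sets(config: SyntheticConfig, n_random: int = 10) -> dict[str, list[str]]:
    """GMT-style gene sets: program-derived sets (several with names containing
    MESEN/FIBRO, mirroring the mesenchymal/fibroblast name filter) plus random
    background sets."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bp = _Blueprint(config, rng)
    lineage = bp.programs["lineage"]
    fib = bp.programs["fib_common"] + bp.programs["fib_early"]
    sets = {
        "GOBP_COLLAGEN_FIBRIL_ORGANIZATION_SYN": list(lineage[:25]),
        "GOBP_MESENCHYME_DEVELOPMENT_SYN": list(lineage[10:30]) + list(fib[:10]),
        "GOBP_FIBROBLAST_ACTIVATION_SYN": list(fib[:30]),
        "HALLMARK_ANGIOGENESIS_SYN": list(bp.programs["type_endothelial"][:25]),
    }
    universe = np.array(bp.genes)
    for i in range(n_random):
        sets[f"GOBP_RANDOM_SET_{i + 1}_SYN"] = [
            str(g) for g in rng.choice(universe, size=25, replace=False)
        ]
    return sets


def _calibrated_censoring_rate(lam0: float, beta: float, target: float) -> float:
    """Exponential-censoring rate giving the requested marginal censor rate.

    With signature s ~ N(0,1), hazard lam0*exp(beta*s) and censoring C ~
    Exp(c), P(censored) = E_s[c / (c + lam0*exp(beta*s))]; solve for c by
    Gauss-Hermite quadrature + root bracketing.
    """
    nodes, wts = np.polynomial.hermite_e.hermegauss(61)
    wts = wts / wts.sum()
    lam = lam0 * np.exp(beta * nodes)

    def p_cens(c: float) -> float:
        return float(np.sum(wts * c / (c + lam)))

    lo, hi = lam0 * 1e-8, lam0 * 1e8
    return brentq(lambda c: p_cens(c) - target, lo, hi)


@dataclass
class BulkCohort:
    """Bulk expression (samples x genes) with clinical annotations."""

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            raise ConfigError("duplicate bulk sample ids")
        if not self.expression.index.equals(self.clinical.index):
            raise ConfigError("expression and clinical tables must share sample ids")


def generate_bulk_cohort(config: SyntheticConfig) -> tuple[BulkCohort, pd.Series]:
    """Bulk cohort with a latent signature driving expression, stage and hazard.

    Expression is ``2**(base + coef*s + noise)`` (positive, log-normal-like);
    survival times are exponential with hazard ``lam0 * exp(hazard_beta*s)``
    under independent exponential censoring calibrated to ``censor_rate``.
    Returns the cohort and the true per-sample signature.
    """
    config.validate()
    if config.bulk_n < 20:
        raise ConfigError("bulk_n must be at least 20")
    rng = np.random.default_rng(config.seed + 1_000_003)
    bp = _Blueprint(config, np.random.default_rng(config.seed))
    n = config.bulk_n
    genes = bp.genes
    sig_genes = sorted(
        set(bp.programs["lineage"]) - {p[1] for p in config.lr_pairs_planted}
    ) + [config.marker_gene_id]
    s = rng.normal(0.0, 1.0, size=n)
    base = rng.normal(3.0, 1.5, size=len(genes))
    log_expr = base[None, :] + rng.normal(0.0, 1.0, size=(n, len(genes)))
    cols = [bp.gene_index[g] for g in sig_genes]
    log_expr[:, cols] += s[:, None]
    expr = 2.0 ** log_expr

    lam0 = 1.0 / 1000.0
    T = rng.exponential(1.0 / (lam0 * np.exp(config.hazard_beta * s)))
    if config.censor_rate > 0:
        c_rate = _calibrated_censoring_rate(lam0, config.hazard_beta, config.censor_rate)
        C = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    stage_high = rng.random(n) < expit(s)
    sample_ids = [f"B{i:04d}" for i in range(n)]
    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "stage": np.where(stage_high, "Stage 3", "Stage 1"),
            "age": rng.normal(65.0, 10.0, size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "cancer_type": "SYN",
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    expression = pd.DataFrame(
        expr, index=clinical.index, columns=pd.Index(genes, name="gene")
    )
    truth = pd.Series(s, index=clinical.index, name="signature")
    return BulkCohort(expression=expression, clinical=clinical), truth
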