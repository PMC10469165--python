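"""End-to-end driver reproducing the discovery workflow on synthetic data.

Stage order mirrors the discovery design: simulate (or load) -> per-sample QC
and normalization -> whole-sample clustering -> cell typing and fibroblast
annotation -> per-sample CAF subclustering on common variable features ->
cross-sample subtype matching by CCA -> robust markers -> pseudotime and
lineage-gene selection -> ligand-receptor cross-talk -> preranked enrichment
-> bulk signature score and survival. Each stage writes its tables under the
run directory with a provenance header; a completed run directory is left
untouched on rerun. All computation is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from caflineage import __version__, annotate, clinical, crosstalk, enrichment, io, qc
from caflineage import lineage as lineage_mod
from caflineage import simulate, subtypes
from caflineage.config import PipelineConfig
from caflineage.errors import CaflineageError

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "qc",
    "annotate",
    "subcluster",
    "match",
    "markers",
    "pseudotime",
    "lineage_genes",
    "crosstalk",
    "gsea",
    "clinical",
)


@dataclass
class RunState:
    """In-memory state threaded through the pipeline stages."""

    config: PipelineConfig
    outdir: Path
    adatas: list[ad.AnnData] = field(default_factory=list)
    truth: simulate.GroundTruth | None = None
    reference: pd.DataFrame | None = None
    lr_table: pd.DataFrame | None = None
    gene_sets: dict[str, list[str]] | None = None
    cell_table: pd.DataFrame | None = None
    common_features: list[str] | None = None
    correspondence: subtypes.CorrespondenceMap | None = None
    lineage_subtype: str | None = None
    marker_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    lineage_markers: pd.DataFrame | None = None
    pseudotime: dict[str, pd.Series] = field(default_factory=dict)
    rho_table: pd.DataFrame | None = None
    positive_fractions: pd.DataFrame | None = None
    lineage_genes: pd.DataFrame | None = None
    interactions: dict[str, pd.DataFrame] = field(default_factory=dict)
    common_lr: set | None = None
    frequency_test: dict | None = None
    enrichment_table: pd.DataFrame | None = None
    clinical_results: dict | None = None
    summary: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return [str(a.obs["sample"].iloc[0]) for a in self.adatas]

    def _prov(self) -> str:
        return io.provenance_line(__version__, self.config.digest())

    def write(self, df: pd.DataFrame, rel: str, index: bool = True) -> None:
        io.write_table(df, self.outdir / rel, provenance=self._prov(), index=index)


def stage_simulate(state: RunState) -> None:
    cfg = state.config.synthetic
    adatas, truth = simulate.generate_multisample_sc(cfg)
    state.adatas = adatas
    state.truth = truth
    state.reference = simulate.generate_reference_profiles(cfg)
    state.lr_table = simulate.generate_lr_database(cfg)
    state.gene_sets = simulate.generate_gene_sets(cfg)
    d = state.outdir
    for a in adatas:
        io.write_10x(a, d / "counts" / str(a.obs["sample"].iloc[0]))
    io.write_cell_metadata(adatas, d / "cells.tsv")
    state.write(state.reference, "reference_profiles.tsv")
    state.write(state.lr_table, "lr_pairs.tsv", index=False)
    io.write_gmt(state.gene_sets, d / "gene_sets.gmt")
    state.write(truth.cells, "truth/cells.tsv")


def stage_qc(state: RunState) -> None:
    p = state.config.qc
    filtered = []
    reports = []
    for a in state.adatas:
        rep = qc.qc_report(
            a, p.min_genes, p.max_genes, p.min_umi, p.max_mito, mito_prefix=p.mito_prefix
        )
        rep.insert(0, "sample", str(a.obs["sample"].iloc[0]))
        reports.append(rep)
        f = qc.filter_cells(
            a, p.min_genes, p.max_genes, p.min_umi, p.max_mito, mito_prefix=p.mito_prefix
        )
        f = qc.log_normalize(f, p.scale_factor)
        log.info("QC %s: %d -> %d cells", a.obs["sample"].iloc[0], a.n_obs, f.n_obs)
        filtered.append(f)
    state.adatas = filtered
    state.write(pd.concat(reports), "qc_report.tsv")


def stage_annotate(state: RunState) -> None:
    tables = []
    for a in state.adatas:
        labels = annotate.classify_reference(a, state.reference)
        tables.append(annotate.annotate_fibroblasts(a, labels))
    state.cell_table = pd.concat(tables)
    state.write(state.cell_table, "cell_table.tsv")


def stage_subcluster(state: RunState) -> None:
    """Subcluster the CAFs of each sample on common variable features."""
    vp = state.config.variable_genes
    cp = state.config.clustering
    var_sets = []
    caf_views = []
    for a in state.adatas:
        cells = state.cell_table.loc[a.obs_names]
        caf = a[(cells["fib_class"] == "CAF").to_numpy()]
        caf_views.append(caf)
        var_sets.append(
            qc.select_variable_genes(
                caf, vp.min_mean, vp.max_mean, vp.min_dispersion, vp.n_top, vp.n_bins
            )
        )
    state.common_features = qc.common_variable_features(var_sets)
    log.info("common variable features: %d", len(state.common_features))
    for a, caf in zip(state.adatas, caf_views):
        emb, _ = qc.scale_and_pca(
            caf, state.common_features, n_pcs=cp.n_pcs, clip=cp.clip
        )
        labels = qc.snn_cluster(
            emb, k_neighbors=min(cp.k_neighbors, caf.n_obs - 1),
            resolution=cp.caf_resolution, seed=state.config.seed, prune=cp.snn_prune,
        )
        state.cell_table.loc[caf.obs_names, "cluster"] = labels
    state.write(state.cell_table, "cell_table.tsv")


def _caf_cluster_profiles(state: RunState) -> dict[str, dict[int, np.ndarray]]:
    profiles: dict[str, dict[int, np.ndarray]] = {}
    feats = state.common_features
    for a in state.adatas:
        sample = str(a.obs["sample"].iloc[0])
        cells = state.cell_table.loc[a.obs_names]
        cols = a.var_names.get_indexer(feats)
        nm = qc.lognorm(a)[:, cols]
        profiles[sample] = {}
        caf = cells["fib_class"] == "CAF"
        for cl in sorted(cells.loc[caf, "cluster"].unique()):
            rows = np.flatnonzero((caf & (cells["cluster"] == cl)).to_numpy())
            if len(rows) >= 3:
                profiles[sample][int(cl)] = np.asarray(nm[rows].todense()).T
    return profiles


def stage_match(state: RunState) -> None:
    profiles = _caf_cluster_profiles(state)
    cmap = subtypes.match_clusters(profiles)
    marker = state.config.synthetic.marker_gene_id
    marker_means: dict[tuple[str, int], float] = {}
    for a in state.adatas:
        if marker not in set(a.var_names):
            break
        sample = str(a.obs["sample"].iloc[0])
        cells = state.cell_table.loc[a.obs_names]
        col = a.var_names.get_loc(marker)
        vals = np.asarray(qc.lognorm(a)[:, col].todense()).ravel()
        caf = (cells["fib_class"] == "CAF").to_numpy()
        for cl in np.unique(cells["cluster"][caf]):
            sel = caf & (cells["cluster"] == cl).to_numpy()
            marker_means[(sample, int(cl))] = float(vals[sel].mean())
    else:
        cmap = subtypes.name_subtype_by_marker(cmap, marker_means, marker)
    state.correspondence = cmap
    for row in cmap.assignment.itertuples():
        sel = (
            (state.cell_table["sample"] == row.sample)
            & (state.cell_table["cluster"] == row.cluster)
            & (state.cell_table["fib_class"] == "CAF")
        )
        state.cell_table.loc[sel, "subtype"] = row.subtype
    marked = cmap.assignment["subtype"].str.endswith("+")
    state.lineage_subtype = (
        cmap.assignment.loc[marked, "subtype"].iloc[0] if marked.any() else None
    )
    state.write(cmap.assignment, "correspondence.tsv", index=False)
    state.write(cmap.pairs, "correspondence_pairs.tsv", index=False)
    state.write(state.cell_table, "cell_table.tsv")


def stage_markers(state: RunState) -> None:
    mp = state.config.markers
    all_subtypes = sorted(
        s for s in state.cell_table["subtype"].unique() if s not in ("", "NF")
    )
    per_subtype: dict[str, pd.DataFrame] = {}
    for st in all_subtypes:
        de_tables = {}
        for a in state.adatas:
            cells = state.cell_table.loc[a.obs_names]
            caf = (cells["fib_class"] == "CAF").to_numpy()
            in_st = caf & (cells["subtype"] == st).to_numpy()
            out_st = caf & ~in_st
            if in_st.sum() < 3 or out_st.sum() < 3:
                continue
            de = subtypes.wilcoxon_de(
                qc.lognorm(a), a.var_names,
                np.flatnonzero(in_st), np.flatnonzero(out_st),
                min_positive_fraction=mp.min_positive_fraction,
                pseudocount=mp.pseudocount,
            )
            de_tables[str(a.obs["sample"].iloc[0])] = de
        if len(de_tables) >= 2:
            per_subtype[st] = subtypes.robust_markers(de_tables, top_n=mp.top_n)
    state.marker_tables = per_subtype
    if state.lineage_subtype and state.lineage_subtype in per_subtype:
        state.lineage_markers = per_subtype[state.lineage_subtype]
    rows = []
    for st, tab in per_subtype.items():
        t = tab.reset_index()
        t.insert(0, "subtype", st)
        rows.append(t)
    if rows:
        state.write(pd.concat(rows, ignore_index=True), "robust_markers.tsv", index=False)


def stage_pseudotime(state: RunState) -> None:
    lp = state.config.lineage
    for a in state.adatas:
        sample = str(a.obs["sample"].iloc[0])
        cells = state.cell_table.loc[a.obs_names]
        fib = (cells["fib_class"].isin(["CAF", "NF"])).to_numpy()
        groups = np.where(
            cells["fib_class"].to_numpy() == "NF", "NF", cells["subtype"].to_numpy()
        )[fib]
        nm = qc.lognorm(a)[np.flatnonzero(fib)]
        ordering = lineage_mod.select_ordering_genes(
            nm, a.var_names, groups, alpha=lp.ordering_alpha
        )
        pt = lineage_mod.fit_pseudotime(
            nm, a.var_names, ordering, groups, seed=state.config.seed
        )
        state.pseudotime[sample] = pd.Series(
            pt, index=a.obs_names[fib], name="pseudotime"
        )
        state.cell_table.loc[a.obs_names[fib], "pseudotime"] = pt
    pt_table = state.cell_table.loc[
        state.cell_table["pseudotime"].notna(), ["sample", "pseudotime"]
    ]
    state.write(pt_table, "pseudotime.tsv")


def stage_lineage_genes(state: RunState) -> None:
    lp = state.config.lineage
    per_sample = {}
    pf_tables = []
    for a in state.adatas:
        sample = str(a.obs["sample"].iloc[0])
        cells = state.cell_table.loc[a.obs_names]
        fib = (cells["fib_class"].isin(["CAF", "NF"])).to_numpy()
        nm = qc.lognorm(a)[np.flatnonzero(fib)]
        pt = state.pseudotime[sample].loc[a.obs_names[fib]].to_numpy()
        per_sample[sample] = (nm, a.var_names, pt)
        pf_tables.append(annotate.positive_fraction_table(a, cells))
    state.rho_table = lineage_mod.pseudotime_gene_correlation(per_sample)
    state.positive_fractions = annotate.pooled_positive_fraction_table(pf_tables)
    state.lineage_genes = lineage_mod.lineage_specific_genes(
        state.rho_table,
        state.positive_fractions,
        caf_min_frac=lp.caf_min_frac,
        nf_max_frac=lp.nf_max_frac,
        rho_min=lp.rho_min,
    )
    state.write(state.rho_table, "pseudotime_correlation.tsv")
    state.write(state.lineage_genes, "lineage_genes.tsv")


def _interaction_groups(state: RunState, a: ad.AnnData) -> pd.Series:
    """Group partition for cross-talk: cell types by classifier, CAFs by
    subtype (tumor epithelial cells labelled Cancer)."""
    cells = state.cell_table.loc[a.obs_names]
    g = cells["classifier_label"].astype(str).copy()
    epi = g == "epithelial"
    g[epi & (cells["tissue"] == "tumor")] = "Cancer"
    caf = cells["fib_class"] == "CAF"
    g[caf] = "CAF_" + cells.loc[caf, "subtype"].astype(str)
    g[(cells["fib_class"] == "NF")] = "NF"
    return g


def stage_crosstalk(state: RunState) -> None:
    cp = state.config.crosstalk
    rng = np.random.default_rng(state.config.seed + 17)
    for a in state.adatas:
        sample = str(a.obs["sample"].iloc[0])
        groups = _interaction_groups(state, a)
        state.interactions[sample] = crosstalk.sample_interactions(
            qc.lognorm(a), a.var_names, groups, state.lr_table,
            alpha=cp.alpha, n_perm=cp.n_perm,
            seed=int(rng.integers(2**31 - 1)),
            min_group_size=cp.min_group_size, sample=sample,
        )
    state.common_lr = crosstalk.common_interactions(state.interactions)
    if state.lineage_subtype:
        lin_group = f"CAF_{state.lineage_subtype}"
        others = sorted(
            {
                f"CAF_{s}"
                for s in state.cell_table["subtype"].unique()
                if s not in ("", "NF", state.lineage_subtype)
            }
        )
        lin_in, oth_in = [], []
        for sample, tab in state.interactions.items():
            lin_in.append(crosstalk.interaction_counts(tab, lin_group)[0])
            per_other = [
                crosstalk.interaction_counts(tab, og)[0] for og in others
            ]
            oth_in.append(float(np.mean(per_other)) if per_other else 0.0)
        if len(lin_in) >= 2:
            state.frequency_test = crosstalk.interaction_frequency_compare(
                np.array(lin_in), np.array(oth_in), alternative="greater"
            )
    all_tabs = pd.concat(state.interactions.values(), ignore_index=True)
    state.write(all_tabs, "interactions.tsv", index=False)


def stage_gsea(state: RunState) -> None:
    ep = state.config.enrichment
    if not state.lineage_subtype:
        log.warning("no marker-named lineage subtype; skipping enrichment")
        return
    rng = np.random.default_rng(state.config.seed + 29)
    results = []
    for a in state.adatas:
        cells = state.cell_table.loc[a.obs_names]
        caf = (cells["fib_class"] == "CAF").to_numpy()
        pos = caf & (cells["subtype"] == state.lineage_subtype).to_numpy()
        neg = caf & ~pos
        de = subtypes.wilcoxon_de(
            qc.lognorm(a), a.var_names, np.flatnonzero(pos), np.flatnonzero(neg)
        )
        ranking = enrichment.rank_genes_for_gsea(de)
        for name, genes in state.gene_sets.items():
            try:
                results.append(
                    enrichment.preranked_gsea(
                        ranking, genes, weight=ep.weight, n_perm=ep.n_perm,
                        seed=int(rng.integers(2**31 - 1)), name=name,
                        sample=str(a.obs["sample"].iloc[0]),
                    )
                )
            except CaflineageError as exc:
                log.info("skipping gene set %s: %s", name, exc)
    state.enrichment_table = enrichment.average_enrichment(results)
    state.write(state.enrichment_table, "enrichment.tsv")


def stage_clinical(state: RunState) -> None:
    cohort, bulk_truth = simulate.generate_bulk_cohort(state.config.synthetic)
    if state.truth is not None:
        state.truth.bulk_signature = bulk_truth
    if state.lineage_markers is not None and len(state.lineage_markers) >= 5:
        signature = list(
            state.lineage_markers[state.lineage_markers["mean_log2fc"] > 0].index
        )
    else:  # fall back to the planted signature definition
        signature = list(state.truth.signature_genes)
    score = clinical.signature_score(cohort, signature)
    abundance = clinical.caf_abundance(cohort, signature)
    cp = state.config.clinical
    surv = clinical.survival_by_signature(
        cohort, score, split_rule=cp.split_rule, adjusters=tuple(cp.adjusters)
    )
    stage_high = cohort.clinical["stage"].map(clinical.bin_stage) == "high"
    stage_cmp = clinical.group_compare(
        score[stage_high].to_numpy(), score[~stage_high].to_numpy()
    )
    props = clinical.subtype_proportion_by_stage(
        state.cell_table, state.lineage_subtype or ""
    )
    state.clinical_results = {
        "cohort": cohort,
        "signature": signature,
        "score": score,
        "abundance": abundance,
        "survival": surv,
        "stage_compare": stage_cmp,
        "stage_proportions": props,
    }
    out = pd.DataFrame({"signature_score": score, "caf_abundance": abundance})
    state.write(out, "bulk_scores.tsv")
    state.write(surv["cox_continuous"].table, "cox_continuous.tsv")
    state.write(props, "stage_proportions.tsv")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "annotate": stage_annotate,
    "subcluster": stage_subcluster,
    "match": stage_match,
    "markers": stage_markers,
    "pseudotime": stage_pseudotime,
    "lineage_genes": stage_lineage_genes,
    "crosstalk": stage_crosstalk,
    "gsea": stage_gsea,
    "clinical": stage_clinical,
}


def _summarize(state: RunState) -> dict:
    s: dict = {"samples": state.samples, "lineage_subtype": state.lineage_subtype}
    if state.lineage_markers is not None:
        s["lineage_robust_markers"] = list(state.lineage_markers.index[:20])
    ct = state.cell_table
    if ct is not None and state.lineage_subtype:
        frac = {}
        for sample in state.samples:
            caf = ct[(ct["sample"] == sample) & (ct["fib_class"] == "CAF")]
            frac[sample] = float((caf["subtype"] == state.lineage_subtype).mean())
        s["lineage_fraction_of_cafs"] = frac
    if state.lineage_genes is not None and len(state.lineage_genes):
        s["top_lineage_gene"] = str(state.lineage_genes.index[0])
        s["lineage_genes"] = list(state.lineage_genes.index[:20])
    if state.frequency_test:
        s["interaction_frequency_test"] = state.frequency_test
    if state.clinical_results:
        surv = state.clinical_results["survival"]
        s["logrank_p"] = surv.get("logrank_p")
        s["cox_score_beta"] = float(
            surv["cox_continuous"].table.loc["score", "beta"]
        )
        s["cox_score_p"] = float(surv["cox_continuous"].table.loc["score", "p"])
    return s


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> RunState:
    """Execute the pipeline stages in order, writing outputs under ``outdir``.

    A directory containing a ``summary.json`` is considered complete and is
    not touched again unless ``force`` is set. Stage failure raises with the
    failing stage named; earlier outputs are preserved.
    """
    outdir = Path(outdir)
    state = RunState(config=config, outdir=outdir)
    summary_path = outdir / "summary.json"
    if summary_path.exists() and not force:
        log.info("run directory %s already complete; no-op", outdir)
        state.summary = json.loads(summary_path.read_text())
        return state
    outdir.mkdir(parents=True, exist_ok=True)
    config.snapshot(outdir / "config_resolved.yaml")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise CaflineageError(f"unknown stages: {sorted(unknown)}")
    for name in STAGES:
        if name not in stages:
            continue
        log.info("--- stage %s ---", name)
        try:
            _STAGE_FUNCS[name](state)
        except Exception as exc:
            raise CaflineageError(f"stage '{name}' failed: {exc}") from exc
    state.summary = _summarize(state)
    if set(stages) == set(STAGES):
        summary_path.write_text(json.dumps(state.summary, indent=2, default=str))
    return state
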