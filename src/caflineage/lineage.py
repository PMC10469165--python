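"""Pseudotime over fibroblasts and the lineage-specific gene selection rule.

The pseudotime itself is deliberately simple and pluggable: the downstream
quantity of interest is the per-gene Spearman correlation between expression
and pseudotime (averaged over samples) and the selection rule combining that
correlation with common-expression filters on CAFs and NFs; any trajectory
method producing a per-fibroblast scalar can be substituted via a TSV.

The built-in method ("principal-curve-lite") selects ordering genes by a
Kruskal-Wallis test across the subtype + NF groups (BH-adjusted p < alpha),
embeds the fibroblasts in 2 principal components on those genes, threads a
polyline through the group centroids ordered by distance from the NF
centroid, and reads pseudotime as arc-length position of each cell's
projection onto the polyline, anchored so that NFs sit at the origin.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from caflineage.errors import DataError
from caflineage.qc import scale_genes
from caflineage.subtypes import _dense
from statsmodels.stats.multitest import multipletests
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


def select_ordering_genes(
    nm: np.ndarray | sp.spmatrix,
    genes: pd.Index | list[str],
    groups: np.ndarray,
    alpha: float = 0.001,
) -> list[str]:
    """Genes varying across the fibroblast groups (CAF subtypes + NF).

    Per-gene Kruskal-Wallis test across groups, BH adjusted; keep adjusted
    p < alpha.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DataError("need at least two fibroblast groups")
    X = _dense(nm)
    genes = pd.Index(genes)
    idx_by_group = [np.flatnonzero(groups == g) for g in labels]
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        samples = [X[idx, j] for idx in idx_by_group]
        flat = X[:, j]
        if np.all(flat == flat[0]):
            continue
        try:
            pvals[j] = stats.kruskal(*samples).pvalue
        except ValueError:  # all values identical within the test
            pvals[j] = 1.0
    padj = multipletests(pvals, method="fdr_bh")[1]
    selected = list(genes[padj < alpha])
    if len(selected) < 10:
        raise DataError(
            f"only {len(selected)} ordering genes at alpha={alpha}; relax alpha"
        )
    return selected


def _project_polyline(points: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's orthogonal projection onto the
    polyline through ``nodes``."""
    seg_vec = np.diff(nodes, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_start = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    best_d = np.full(points.shape[0], np.inf)
    best_s = np.zeros(points.shape[0])
    for i, (a, v, L, s0) in enumerate(zip(nodes[:-1], seg_vec, seg_len, seg_start)):
        if L == 0:
            continue
        tt = np.clip((points - a) @ v / L**2, 0.0, 1.0)
        proj = a + tt[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_s[upd] = s0 + tt[upd] * L
    return best_s


def fit_pseudotime(
    nm: np.ndarray | sp.spmatrix,
    genes: pd.Index | list[str],
    ordering_genes: list[str],
    groups: np.ndarray,
    nf_label: str = "NF",
    anchor_group: str | None = None,
    seed: int = 0,
) -> pd.Series | np.ndarray:
    """Principal-curve-lite pseudotime for fibroblast cells.

    ``nm`` holds the fibroblasts (cells x genes), ``groups`` their subtype/NF
    labels. Pseudotime is anchored at the NF group (or ``anchor_group`` if no
    NFs are present) so the anchor mean is lowest. Returns one non-negative
    scalar per cell.
    """
    if len(ordering_genes) < 10:
        raise DataError("need at least 10 ordering genes")
    groups = np.asarray(groups)
    anchor = nf_label if (groups == nf_label).any() else anchor_group
    if anchor is None or not (groups == anchor).any():
        raise DataError("no NF cells: supply anchor_group to orient the trajectory")
    genes = pd.Index(genes)
    cols = genes.get_indexer(ordering_genes)
    if (cols < 0).any():
        raise DataError("ordering genes missing from the matrix")
    Z = scale_genes(sp.csr_matrix(_dense(nm)[:, cols]))
    emb = PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(Z)

    labels = pd.unique(groups)
    centroids = np.stack([emb[groups == g].mean(axis=0) for g in labels])
    nf_c = centroids[list(labels).index(anchor)]
    order = np.argsort(np.linalg.norm(centroids - nf_c, axis=1))
    nodes = centroids[order]
    pt = _project_polyline(emb, nodes)
    # anchor: NF mean below CAF mean, origin at zero
    other = groups != anchor
    if other.any() and pt[groups == anchor].mean() > pt[other].mean():
        pt = pt.max() - pt
    pt = pt - pt.min()
    return pt


def pseudotime_gene_correlation(
    per_sample: dict[str, tuple[np.ndarray | sp.spmatrix, pd.Index, np.ndarray]],
) -> pd.DataFrame:
    """Mean Spearman correlation between pseudotime and expression per gene.

    ``per_sample[sample] = (nm, genes, pseudotime)`` over that sample's
    fibroblasts. The gene universe is the intersection across samples.
    Zero-variance genes get rho = 0 with ``flat=True``.
    """
    if not per_sample:
        raise DataError("no samples given")
    universe: pd.Index | None = None
    for _, (nm, genes, pt) in per_sample.items():
        universe = pd.Index(genes) if universe is None else universe.intersection(genes)
    rhos = []
    flat_any = np.zeros(len(universe), dtype=bool)
    for sample, (nm, genes, pt) in per_sample.items():
        pt = np.asarray(pt, dtype=float)
        if len(pt) != _dense(nm).shape[0] or np.any(~np.isfinite(pt)):
            log.warning("skipping sample %s: pseudotime missing or non-finite", sample)
            continue
        X = _dense(nm)[:, pd.Index(genes).get_indexer(universe)]
        r = _spearman_vector(X, pt)
        flat = ~np.isfinite(r)
        flat_any |= flat
        r[flat] = 0.0
        rhos.append(r)
    if not rhos:
        raise DataError("no sample had usable pseudotime")
    mean_rho = np.mean(np.stack(rhos), axis=0)
    return pd.DataFrame({"mean_rho": mean_rho, "flat": flat_any}, index=universe)


def _spearman_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlation of each column of X with y (NaN if degenerate)."""
    ry = stats.rankdata(y)
    rX = stats.rankdata(X, axis=0)
    ry_c = ry - ry.mean()
    rX_c = rX - rX.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(rX_c, axis=0) * np.linalg.norm(ry_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = rX_c.T @ ry_c / denom
    r[denom == 0] = np.nan
    return r


def lineage_specific_genes(
    rho_table: pd.DataFrame,
    positive_fractions: pd.DataFrame,
    caf_min_frac: float = 0.25,
    nf_max_frac: float = 0.05,
    rho_min: float = 0.3,
) -> pd.DataFrame:
    """CAF lineage genes: common in CAFs, absent from NFs, pseudotime-correlated.

    Keeps genes with CAF positive fraction >= caf_min_frac, NF positive
    fraction <= nf_max_frac and mean Spearman rho >= rho_min, ranked by
    decreasing rho. An empty result is allowed.
    """
    genes = rho_table.index.intersection(positive_fractions.index)
    t = rho_table.loc[genes].join(positive_fractions.loc[genes])
    sel = t[
        (t["caf_frac"] >= caf_min_frac)
        & (t["nf_frac"] <= nf_max_frac)
        & (t["mean_rho"] >= rho_min)
    ]
    return sel.sort_values("mean_rho", ascending=False)


def marker_set_correlation(
    nm: np.ndarray | sp.spmatrix,
    genes: pd.Index | list[str],
    gene: str,
    marker_sets: dict[str, list[str]],
) -> pd.Series:
    """Spearman correlation of one gene with each marker set's mean expression.

    The correlation is over the cells of ``nm`` (caller chooses the subset,
    e.g. all CAFs); set genes absent from the matrix are dropped, a fully
    absent set is an error.
    """
    genes = pd.Index(genes)
    if gene not in set(genes):
        raise DataError(f"gene {gene!r} not in matrix")
    X = _dense(nm)
    g = X[:, genes.get_loc(gene)]
    out = {}
    for name, members in marker_sets.items():
        cols = genes.get_indexer([m for m in members if m in set(genes)])
        if len(cols) == 0:
            raise DataError(f"marker set {name!r} has no genes in the matrix")
        mean_expr = X[:, cols].mean(axis=1)
        rho = stats.spearmanr(g, mean_expr).statistic
        out[name] = float(rho)
    return pd.Series(out, name=gene)
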