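"""Cell filtering, log-normalization, variable features, PCA and SNN clustering.

All bounds follow the filtering rule exactly: cells with <= min_genes or
>= max_genes detected genes, <= min_umi total counts, or a mitochondrial
fraction >= max_mito are removed (exclusive retention bounds).
"""

from __future__ import annotations

import logging

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from caflineage.errors import DataError

log = logging.getLogger(__name__)

LOGNORM_LAYER = "lognorm"


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    return sp.csr_matrix(adata.X)


def cell_qc_metrics(adata: ad.AnnData, mito_genes: list[str] | None = None,
                    mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell detected genes, UMI totals and mitochondrial fraction."""
    X = _counts(adata)
    n_genes = X.getnnz(axis=1)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    if mito_genes is None:
        mito_mask = adata.var_names.str.startswith(mito_prefix)
    else:
        mito_mask = adata.var_names.isin(mito_genes)
    mito_umi = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes, "n_umi": n_umi, "mito_frac": mito_frac},
        index=adata.obs_names,
    )


def filter_cells(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    min_umi: int = 1000,
    max_mito: float = 0.20,
    mito_genes: list[str] | None = None,
    mito_prefix: str = "MT-",
) -> ad.AnnData:
    """Remove low-quality cells; genes are left unchanged.

    A cell is retained iff min_genes < detected genes < max_genes,
    UMI total > min_umi and mitochondrial fraction < max_mito.
    """
    if min(min_genes, max_genes, min_umi) < 0 or max_mito < 0:
        raise DataError("QC thresholds must be non-negative")
    qc = cell_qc_metrics(adata, mito_genes=mito_genes, mito_prefix=mito_prefix)
    keep = (
        (qc["n_genes"] > min_genes)
        & (qc["n_genes"] < max_genes)
        & (qc["n_umi"] > min_umi)
        & (qc["mito_frac"] < max_mito)
    ).to_numpy()
    if not keep.any():
        log.warning("filter_cells removed every cell of %s", adata.obs.get("sample"))
    return adata[keep].copy()


def qc_report(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    min_umi: int = 1000,
    max_mito: float = 0.20,
    mito_genes: list[str] | None = None,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Per-cell QC table with pass/fail and the first failing rule."""
    qc = cell_qc_metrics(adata, mito_genes=mito_genes, mito_prefix=mito_prefix)
    reasons = np.array([""] * adata.n_obs, dtype=object)
    reasons[(qc["mito_frac"] >= max_mito).to_numpy()] = "high_mito"
    reasons[(qc["n_umi"] <= min_umi).to_numpy()] = "low_umi"
    reasons[(qc["n_genes"] >= max_genes).to_numpy()] = "high_genes"
    reasons[(qc["n_genes"] <= min_genes).to_numpy()] = "low_genes"
    qc["status"] = np.where(reasons == "", "pass", "fail")
    qc["reason"] = reasons
    return qc


def log_normalize(adata: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Library-size log-normalization: ln(1 + scale * count / cell total).

    Writes the result to ``layers['lognorm']`` (counts stay in ``.X``) and
    records the provenance in ``uns``. Zero-total cells are an error: they
    should be impossible after filtering.
    """
    if scale_factor <= 0:
        raise DataError("scale_factor must be positive")
    X = _counts(adata)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise DataError("log_normalize requires every cell total > 0; filter first")
    norm = X.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.layers[LOGNORM_LAYER] = norm
    out.uns["normalization"] = {
        "scale_factor": float(scale_factor),
        "formula": "ln(1 + scale_factor * count / cell_total)",
    }
    return out


def lognorm(adata: ad.AnnData) -> sp.csr_matrix:
    if LOGNORM_LAYER not in adata.layers:
        raise DataError("no 'lognorm' layer: run log_normalize first")
    return sp.csr_matrix(adata.layers[LOGNORM_LAYER])


def select_variable_genes(
    adata: ad.AnnData,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_dispersion: float = 0.5,
    n_top: int = 1000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean/dispersion variable-gene selection on the log-normalized layer.

    Statistics follow the conventional mean-variance recipe for log data:
    per-gene mean and variance of the back-transformed (expm1) values,
    dispersion = variance/mean, the mean reported as log1p(mean), and the
    dispersion z-standardized within ``n_bins`` equal-frequency mean bins.
    Genes with mean strictly inside (min_mean, max_mean) and standardized
    dispersion > min_dispersion are kept, truncated to the ``n_top`` highest
    dispersions. Returns a DataFrame indexed by gene with columns
    mean/dispersion/dispersion_norm, ordered by decreasing dispersion_norm.
    """
    if n_top < 1:
        raise DataError("n_top must be >= 1")
    nm = lognorm(adata)
    back = nm.copy()
    back.data = np.expm1(back.data)
    mean = np.asarray(back.mean(axis=0)).ravel()
    sq = back.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    var *= back.shape[0] / max(back.shape[0] - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), np.nan)
    log_mean = np.log1p(mean)

    df = pd.DataFrame(
        {"mean": log_mean, "dispersion": disp}, index=adata.var_names
    ).dropna()
    # z-standardize dispersion within equal-frequency mean bins
    bins = pd.qcut(df["mean"], q=min(n_bins, max(df.shape[0] // 2, 1)), duplicates="drop")
    grouped = df.groupby(bins, observed=True)["dispersion"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std").replace(0.0, np.nan).fillna(1.0)
    df["dispersion_norm"] = ((df["dispersion"] - mu) / sd).fillna(0.0)

    passing = df[
        (df["mean"] > min_mean)
        & (df["mean"] < max_mean)
        & (df["dispersion_norm"] > min_dispersion)
    ]
    if passing.empty:
        raise DataError("no gene passes the variable-gene cutoffs")
    return passing.sort_values("dispersion_norm", ascending=False).head(n_top)


def common_variable_features(sets: list[pd.DataFrame | list[str]]) -> list[str]:
    """Exact intersection of variable-gene sets across samples.

    Order is by mean rank across the input sets (each set taken in its own
    order), ties broken lexicographically.
    """
    if len(sets) < 2:
        raise DataError("need at least two variable-feature sets to intersect")
    gene_lists = [list(s.index) if isinstance(s, pd.DataFrame) else list(s) for s in sets]
    common = set(gene_lists[0])
    for gl in gene_lists[1:]:
        common &= set(gl)
    if not common:
        raise DataError("variable-feature sets have an empty intersection")
    mean_rank = {
        g: float(np.mean([gl.index(g) for gl in gene_lists])) for g in common
    }
    return sorted(common, key=lambda g: (mean_rank[g], g))


def scale_genes(
    nm: sp.spmatrix, clip: float = 10.0
) -> np.ndarray:
    """Per-gene z-scaling (dense), constant genes set to zero, clipped."""
    X = np.asarray(nm.todense()) if sp.issparse(nm) else np.asarray(nm, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        log.info("scale_genes: %d constant genes set to zero", int(const.sum()))
    sd = np.where(const, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, const] = 0.0
    return np.clip(Z, -clip, clip)


def scale_and_pca(
    adata: ad.AnnData,
    features: list[str],
    n_pcs: int = 20,
    clip: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-scale the selected features and run PCA.

    Returns the cells x n_pcs embedding and the explained variances
    (non-increasing).
    """
    missing = set(features) - set(adata.var_names)
    if missing:
        raise DataError(f"features not in the matrix: {sorted(missing)[:5]}")
    if n_pcs > len(features):
        raise DataError("n_pcs cannot exceed the number of features")
    cols = adata.var_names.get_indexer(features)
    Z = scale_genes(lognorm(adata)[:, cols], clip=clip)
    n_pcs = min(n_pcs, min(Z.shape) - 1) if min(Z.shape) > 1 else 1
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(Z)
    return emb, pca.explained_variance_


def find_elbow(variances: np.ndarray) -> int:
    """Scree-plot elbow: the point farthest from the line joining the first
    and last explained variances (1-based component index)."""
    v = np.asarray(variances, dtype=float)
    if v.size < 3:
        return v.size
    x = np.arange(v.size, dtype=float)
    p0, p1 = np.array([x[0], v[0]]), np.array([x[-1], v[-1]])
    d = p1 - p0
    d /= np.linalg.norm(d)
    rel = np.stack([x, v], axis=1) - p0
    dist = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
    return int(np.argmax(dist)) + 1


def snn_graph(
    embedding: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15
) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell is connected to cells sharing k-nearest-neighbor membership;
    edge weight = Jaccard overlap of the two neighbor sets (self included),
    pruned below ``prune``.
    """
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_neighbors, n)).fit(embedding)
    knn = nn.kneighbors_graph(embedding, mode="connectivity")
    knn = knn.maximum(sp.eye(n, format="csr"))
    shared = (knn @ knn.T).tocoo()  # counts of shared neighbors
    k = np.asarray(knn.sum(axis=1)).ravel()
    union = k[shared.row] + k[shared.col] - shared.data
    jaccard = shared.data / union
    keep = (jaccard >= prune) & (shared.row < shared.col)
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def snn_cluster(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    prune: float = 1 / 15,
) -> np.ndarray:
    """SNN graph + Leiden community detection; deterministic for a fixed seed.

    Returns integer cluster labels ordered by decreasing cluster size.
    """
    n = embedding.shape[0]
    if n < 10:
        raise DataError("need at least 10 cells to cluster")
    if k_neighbors >= n:
        raise DataError("k_neighbors must be smaller than the number of cells")
    g = snn_graph(embedding, k_neighbors=k_neighbors, prune=prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing size for stable downstream naming
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[x] for x in labels])
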