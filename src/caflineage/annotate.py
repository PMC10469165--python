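"""Reference-correlation cell typing, the fibroblast rule, positive cells.

Cell typing is a single-pass rank-correlation classifier: each cell is
labelled with the reference type whose profile has the highest Spearman
correlation with the cell over the reference-variable genes (top quartile by
between-type variance). A cell is then a fibroblast only if it is classified
"fibroblast" AND has a non-zero count for at least one canonical fibroblast
marker; fibroblasts from tumor or border tissue are CAFs, those from normal
tissue NFs. Positivity of a cell for a gene means a non-zero UMI count.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from caflineage.errors import DataError
from caflineage.qc import lognorm

DEFAULT_FIB_MARKERS = ("DCN", "COL3A1", "THY1")
FIBROBLAST_LABEL = "fibroblast"
CAF_TISSUES = ("tumor", "border")


def reference_variable_genes(ref: pd.DataFrame, quantile: float = 0.75) -> list[str]:
    """Genes in the top quartile of between-type variance of the reference."""
    var = ref.var(axis=1)
    cutoff = var.quantile(quantile)
    # relative tolerance so ties straddling the quantile are kept together
    return list(ref.index[var >= cutoff - 1e-9 * max(abs(cutoff), 1.0)])


def classify_reference(
    adata: ad.AnnData, ref: pd.DataFrame, min_shared_genes: int = 50
) -> pd.DataFrame:
    """Label each cell with the best Spearman-correlated reference type.

    Returns a DataFrame (index = cells) with ``classifier_label`` and the
    winning correlation ``classifier_score``. Cells with zero variance over
    the shared genes are labelled "unassigned".
    """
    if ref.shape[1] < 2:
        raise DataError("need at least two reference types")
    shared = [g for g in ref.index if g in set(adata.var_names)]
    if len(shared) < min_shared_genes:
        raise DataError(
            f"only {len(shared)} genes shared between data and reference "
            f"(need >= {min_shared_genes})"
        )
    use = [g for g in reference_variable_genes(ref.loc[shared]) if g in set(shared)]
    cols = adata.var_names.get_indexer(use)
    X = np.asarray(lognorm(adata)[:, cols].todense())
    R = ref.loc[use].to_numpy().T  # types x genes

    cell_ranks = rankdata(X, axis=1)
    ref_ranks = rankdata(R, axis=1)

    def _center_norm(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        n = np.linalg.norm(c, axis=1, keepdims=True)
        return np.divide(c, n, out=np.zeros_like(c), where=n > 0), (n.ravel() > 0)

    cr, cell_ok = _center_norm(cell_ranks)
    rr, _ = _center_norm(ref_ranks)
    corr = cr @ rr.T  # cells x types, Spearman via Pearson on ranks
    best = np.argmax(corr, axis=1)
    labels = np.asarray(ref.columns)[best].astype(object)
    scores = corr[np.arange(corr.shape[0]), best]
    labels[~cell_ok] = "unassigned"
    scores[~cell_ok] = np.nan
    return pd.DataFrame(
        {"classifier_label": labels, "classifier_score": scores}, index=adata.obs_names
    )


def annotate_fibroblasts(
    adata: ad.AnnData,
    labels: pd.DataFrame,
    markers: tuple[str, ...] = DEFAULT_FIB_MARKERS,
) -> pd.DataFrame:
    """Build the per-cell table with the two-condition fibroblast rule.

    is_fibroblast <=> classified fibroblast AND >= 1 marker with a non-zero
    count. fib_class is CAF for tumor- or border-tissue fibroblasts, NF for
    normal-tissue fibroblasts, 'none' otherwise.
    """
    missing = [m for m in markers if m not in set(adata.var_names)]
    if missing:
        raise DataError(f"fibroblast marker gene(s) missing from matrix: {missing}")
    cols = adata.var_names.get_indexer(list(markers))
    X = sp.csr_matrix(adata.X)
    any_marker = np.asarray((X[:, cols] > 0).sum(axis=1)).ravel() > 0
    table = pd.DataFrame(index=adata.obs_names)
    table["sample"] = adata.obs["sample"].to_numpy()
    table["tissue"] = adata.obs["tissue"].to_numpy()
    table["stage"] = adata.obs["stage"].to_numpy()
    table["classifier_label"] = labels.loc[adata.obs_names, "classifier_label"].to_numpy()
    table["is_fibroblast"] = (table["classifier_label"] == FIBROBLAST_LABEL) & any_marker
    fib_class = np.array(["none"] * adata.n_obs, dtype=object)
    is_fib = table["is_fibroblast"].to_numpy()
    tissue = table["tissue"].to_numpy()
    fib_class[is_fib & np.isin(tissue, CAF_TISSUES)] = "CAF"
    fib_class[is_fib & (tissue == "normal")] = "NF"
    table["fib_class"] = fib_class
    table["cluster"] = -1
    table["subtype"] = ""
    table["pseudotime"] = np.nan
    return table


def positive_fraction(
    adata: ad.AnnData, gene: str, cells: pd.Index | list[str]
) -> float:
    """Fraction of the given cells with a non-zero count for the gene."""
    if gene not in set(adata.var_names):
        raise DataError(f"gene {gene!r} not in matrix")
    cells = pd.Index(cells)
    if len(cells) == 0:
        raise DataError("empty cell subset")
    rows = adata.obs_names.get_indexer(cells)
    if (rows < 0).any():
        raise DataError("cell subset contains unknown barcodes")
    col = adata.var_names.get_loc(gene)
    X = sp.csc_matrix(adata.X)
    counts = np.asarray(X[rows, col].todense()).ravel()
    return float(np.mean(counts > 0))


def positive_fraction_table(
    adata: ad.AnnData, cell_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene positive-cell fractions on the CAFs and on the NFs."""
    table = cell_table.loc[cell_table.index.intersection(adata.obs_names)]
    caf = table.index[table["fib_class"] == "CAF"]
    nf = table.index[table["fib_class"] == "NF"]
    if len(caf) == 0 or len(nf) == 0:
        raise DataError("need both CAF and NF cells for the positive-cell table")
    X = sp.csr_matrix(adata.X)
    out = {}
    for name, cells in (("caf_frac", caf), ("nf_frac", nf)):
        rows = adata.obs_names.get_indexer(cells)
        frac = np.asarray((X[rows] > 0).mean(axis=0)).ravel()
        out[name] = frac
    return pd.DataFrame(out, index=adata.var_names)


def pooled_positive_fraction_table(
    tables: list[pd.DataFrame],
) -> pd.DataFrame:
    """Average the per-sample CAF/NF positive-fraction tables (equal weight
    per sample, the cross-sample 'commonly expressed' convention)."""
    if not tables:
        raise DataError("no tables to pool")
    genes = tables[0].index
    for t in tables[1:]:
        genes = genes.intersection(t.index)
    stacked = np.stack([t.loc[genes].to_numpy() for t in tables])
    return pd.DataFrame(stacked.mean(axis=0), index=genes, columns=tables[0].columns)
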