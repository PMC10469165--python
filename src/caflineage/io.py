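"""Readers and writers for the on-disk formats the pipeline exchanges.

Single-cell matrices travel as 10x-style triplets (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, genes x cells in the MTX as the 10x
convention has it); everything tabular is TSV. Tables written by the pipeline
carry a one-line provenance comment (tool version + config hash).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from caflineage.errors import DataError


def write_10x(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write a counts AnnData as matrix.mtx / features.tsv / barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X.T)  # genes x cells on disk, 10x convention
    scipy.io.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    pd.DataFrame({"gene": adata.var_names, "name": adata.var_names}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_10x(indir: str | Path) -> ad.AnnData:
    """Read a 10x triplet directory into a cells x genes AnnData."""
    indir = Path(indir)
    mtx = indir / "matrix.mtx"
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as exc:  # surface the offending file for corrupt inputs
        raise DataError(f"cannot parse MTX file {mtx}: {exc}") from exc
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    mat = sp.csr_matrix(mat.T)
    if mat.shape != (len(barcodes), len(genes)):
        raise DataError(
            f"matrix shape {mat.shape} does not match "
            f"{len(barcodes)} barcodes x {len(genes)} features in {indir}"
        )
    data = mat.data
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise DataError(f"counts in {mtx} must be non-negative integers")
    adata = ad.AnnData(
        X=mat.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(barcodes.astype(str), name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes.astype(str), name="gene")),
    )
    if adata.obs_names.duplicated().any() or adata.var_names.duplicated().any():
        raise DataError(f"duplicate barcodes or gene ids in {indir}")
    return adata


def provenance_line(version: str, config_hash: str) -> str:
    return f"# caflineage v{version} config={config_hash}"


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: str | None = None, index: bool = True
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise DataError(f"malformed GMT line in {path}: {line[:80]!r}")
            sets[parts[0]] = parts[2:]
    return sets


def write_cell_metadata(adatas: list[ad.AnnData], path: str | Path) -> None:
    """Cells-metadata TSV: barcode, sample, tissue, stage for every cell."""
    rows = pd.concat([a.obs[["sample", "tissue", "stage"]] for a in adatas])
    rows.index.name = "barcode"
    write_table(rows, path)
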