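"""Readers and writers: 10x-style MatrixMarket triplets and CSV tables."""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["read_10x_triplet", "write_10x_triplet", "write_table", "read_table"]

SCHEMA_VERSION = "1"


def _find(dir_: Path, names: list[str]) -> Path:
    for name in names:
        for cand in (dir_ / name, dir_ / f"{name}.gz"):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {names} (or .gz) found in {dir_}")


def _open(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path, "rt")


def read_10x_triplet(directory) -> ad.AnnData:
    """Read a 10x-style triplet directory (matrix.mtx[.gz] in genes x cells
    orientation, features/genes.tsv[.gz] with 2 or 3 columns, and
    barcodes.tsv[.gz]) into an AnnData (cells x genes)."""
    dir_ = Path(directory)
    mtx_path = _find(dir_, ["matrix.mtx"])
    feat_path = _find(dir_, ["features.tsv", "genes.tsv"])
    bc_path = _find(dir_, ["barcodes.tsv"])
    try:
        with _open(mtx_path) as fh:
            mat = scipy.io.mmread(_io.StringIO(fh.read()))
    except ValueError as exc:
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    with _open(feat_path) as fh:
        feats = pd.read_csv(fh, sep="\t", header=None)
    with _open(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    n_genes, n_cells = mat.shape
    if len(feats) != n_genes or len(barcodes) != n_cells:
        raise ValueError(
            f"dimension mismatch: matrix is {n_genes} genes x {n_cells} cells "
            f"but features file has {len(feats)} rows and barcodes file "
            f"{len(barcodes)} rows")
    symbols = feats[1] if feats.shape[1] >= 2 else feats[0]
    var = pd.DataFrame({"gene_id": feats[0].astype(str).to_numpy()},
                       index=symbols.astype(str).to_numpy())
    if feats.shape[1] >= 3:
        var["feature_type"] = feats[2].astype(str).to_numpy()
    var.index.name = "gene_symbol"
    X = sp.csr_matrix(mat.T)
    return ad.AnnData(X=X, obs=pd.DataFrame(index=barcodes), var=var)


def write_10x_triplet(adata: ad.AnnData, directory, compress: bool = True) -> None:
    """Write an AnnData as a 10x-style triplet (coordinate integer
    MatrixMarket, 1-based indices, genes x cells)."""
    dir_ = Path(directory)
    dir_.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    mat = sp.coo_matrix(adata.X.T)
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    opener = gzip.open if compress else open
    with opener(dir_ / f"matrix.mtx{suffix}", "wb") as fh:
        fh.write(buf.getvalue())
    gene_ids = (adata.var["gene_id"] if "gene_id" in adata.var
                else pd.Series(adata.var_names, index=adata.var_names))
    feats = pd.DataFrame({
        0: gene_ids.to_numpy(),
        1: adata.var_names,
        2: "Gene Expression",
    })
    with opener(dir_ / f"features.tsv{suffix}", "wt") as fh:
        feats.to_csv(fh, sep="\t", header=False, index=False)
    with opener(dir_ / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """CSV with a schema-version header comment and floats at 10
    significant digits; column order is preserved, no timestamps."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt") as fh:
        fh.write(f"# enspattern-table-schema={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index, float_format="%.10g")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)
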