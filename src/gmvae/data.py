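"""Expression-dataset loading.

The in-memory container is :class:`anndata.AnnData`: ``X`` holds a
cells x genes matrix of log-normalized continuous expression values and
``obs`` holds per-cell categorical metadata (condition, cell type, batch).
Readers are provided for the three common on-disk layouts: h5ad,
MTX + barcodes/features TSVs, and a dense CSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def dense_X(adata: ad.AnnData) -> np.ndarray:
    """Return ``adata.X`` as a dense float64 cells x genes array."""
    X = adata.X
    if scipy.sparse.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=np.float64)


def read_h5ad(path: str | Path) -> ad.AnnData:
    return ad.read_h5ad(path)


def read_mtx_dir(
    path: str | Path,
    matrix: str = "matrix.mtx",
    barcodes: str = "barcodes.tsv",
    features: str = "features.tsv",
    obs_table: str | None = "obs.tsv",
) -> ad.AnnData:
    """Read an MTX directory (genes x cells matrix, 10x convention).

    ``barcodes``/``features`` are one identifier per line; an optional
    ``obs_table`` TSV (indexed by barcode) supplies per-cell metadata.
    """
    path = Path(path)
    M = scipy.io.mmread(path / matrix).tocsr().T  # -> cells x genes
    cells = pd.read_csv(path / barcodes, sep="\t", header=None)[0].astype(str)
    genes = pd.read_csv(path / features, sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=M.astype(np.float64),
        obs=pd.DataFrame(index=cells.values),
        var=pd.DataFrame(index=genes.values),
    )
    if obs_table is not None and (path / obs_table).exists():
        meta = pd.read_csv(path / obs_table, sep="\t", index_col=0, dtype=str)
        adata.obs = adata.obs.join(meta)
    return adata


def read_csv(path: str | Path, obs_path: str | Path | None = None) -> ad.AnnData:
    """Read a dense CSV of cells (rows) x genes (columns), first column the
    cell identifier; optional companion CSV/TSV of per-cell metadata."""
    df = pd.read_csv(path, index_col=0)
    adata = ad.AnnData(
        X=df.to_numpy(dtype=np.float64),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )
    if obs_path is not None:
        sep = "\t" if str(obs_path).endswith((".tsv", ".txt")) else ","
        meta = pd.read_csv(obs_path, sep=sep, index_col=0, dtype=str)
        adata.obs = adata.obs.join(meta)
    return adata


def load_dataset(path: str | Path) -> ad.AnnData:
    """Dispatch on extension: ``.h5ad``, ``.csv``, or an MTX directory."""
    path = Path(path)
    if path.is_dir():
        return read_mtx_dir(path)
    if path.suffix == ".h5ad":
        return read_h5ad(path)
    if path.suffix == ".csv":
        return read_csv(path)
    raise ValueError(f"cannot infer dataset format from {path}")
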