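"""Plain-text readers/writers for the pipeline's on-disk formats.

Fragments: TSV with columns (chrom, start, end, barcode), 0-based half-open.
Peaks: 3+ column BED.  Matrices: MatrixMarket (1-based) with sidecar
features.tsv / barcodes.tsv.  Labels and tables: TSV with header.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode"]


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    frags[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "barcode": str},
    )


def write_bed(intervals: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + [f"col{i}" for i in range(len(names), df.shape[1])]
    return df


def write_matrix(X, features: pd.Index, barcodes: pd.Index, prefix: str | Path) -> None:
    """MTX + features/barcodes sidecars; features are rows."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    M = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    sio.mmwrite(str(prefix) + ".mtx", M.astype(np.int64) if np.issubdtype(M.dtype, np.integer) else M)
    pd.Series(features).to_csv(str(prefix) + ".features.tsv", sep="\t", header=False, index=False)
    pd.Series(barcodes).to_csv(str(prefix) + ".barcodes.tsv", sep="\t", header=False, index=False)


def read_matrix(prefix: str | Path) -> tuple[sp.csr_matrix, pd.Index, pd.Index]:
    prefix = str(prefix)
    M = sp.csr_matrix(sio.mmread(prefix + ".mtx"))
    feats = pd.Index(pd.read_csv(prefix + ".features.tsv", sep="\t", header=None)[0])
    bcs = pd.Index(pd.read_csv(prefix + ".barcodes.tsv", sep="\t", header=None)[0])
    return M, feats, bcs


def write_anndata_mtx(adata: ad.AnnData, prefix: str | Path) -> None:
    """Write an AnnData (cells x features) as a feature-by-cell MTX bundle."""
    write_matrix(adata.X.T, adata.var_names, adata.obs_names, prefix)
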