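"""LSA clustering of a binary 5 kb window-by-cell matrix.

The genome is tiled with fixed windows; a window is 1 for a cell iff at
least one Tn5 insertion site (fragment start or end) falls in it.  After
dropping zero-coverage and the top-5%-coverage windows, the matrix is
log-TF-IDF weighted, reduced by truncated SVD, and cells are clustered on
a shared-neighbor-weighted KNN graph by modularity optimization.
"""

from __future__ import annotations

import warnings

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .genome import ToyGenome


def build_window_matrix(
    frags: pd.DataFrame,
    genome: ToyGenome,
    window: int = 5000,
    barcodes: pd.Index | None = None,
) -> ad.AnnData:
    """Binary cells-x-windows AnnData from a fragment table.

    Both fragment ends count as insertion sites; the last partial window of
    each chromosome is kept.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    if barcodes is None:
        barcodes = pd.Index(sorted(frags["barcode"].unique()))
    frags = frags[frags["barcode"].isin(set(barcodes))]

    chrom_names = list(genome.chrom_sizes)
    n_windows = {c: int(np.ceil(genome.chrom_sizes[c] / window)) for c in chrom_names}
    offsets = {}
    cum = 0
    for c in chrom_names:
        offsets[c] = cum
        cum += n_windows[c]
    total_windows = cum

    bc_codes = pd.Categorical(frags["barcode"], categories=barcodes).codes
    chrom = frags["chrom"].values
    rows_list, cols_list = [], []
    for site in ("start", "end"):
        pos = frags[site].values
        widx = np.empty(len(frags), dtype=np.int64)
        for c, idx in frags.groupby("chrom", sort=False).indices.items():
            w = np.minimum(pos[idx] // window, n_windows[c] - 1)
            widx[idx] = w + offsets[c]
        rows_list.append(bc_codes)
        cols_list.append(widx)
    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    X = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(barcodes), total_windows)
    ).tocsr()
    X.data[:] = 1.0  # binarize

    var_rows = []
    for c in chrom_names:
        for i in range(n_windows[c]):
            var_rows.append((c, i * window, min((i + 1) * window, genome.chrom_sizes[c])))
    var = pd.DataFrame(var_rows, columns=["chrom", "start", "end"])
    var.index = [f"{c}:{s}-{e}" for c, s, e in var_rows]
    return ad.AnnData(X=X, obs=pd.DataFrame(index=barcodes), var=var)


def filter_windows(adata: ad.AnnData, top_fraction: float = 0.05) -> ad.AnnData:
    """Drop zero-coverage windows, then the top 5% by cell coverage.

    Windows are ranked by (coverage descending, window index ascending) and
    the top ceil(5%) of the nonzero windows removed; the stable index
    tie-break makes the cut deterministic even under heavy ties.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix")
    coverage = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    nonzero = coverage > 0
    idx = np.flatnonzero(nonzero)
    cov = coverage[idx]
    quota = int(np.ceil(top_fraction * len(idx)))
    order = np.lexsort((idx, -cov))  # coverage desc, index asc
    drop = set(idx[order[:quota]])
    keep = [i for i in idx if i not in drop]
    out = adata[:, keep].copy()
    out.uns["window_filter"] = {
        "n_zero_dropped": int((~nonzero).sum()),
        "n_top_dropped": quota,
        "n_kept": len(keep),
    }
    return out


def log_tfidf(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Weight entries as ln(1 + scale * tf * idf).

    tf = x / per-cell total; idf = n_cells / per-window cell count.  Cells
    with no accessible windows are dropped with a warning.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    cell_tot = np.asarray(X.sum(axis=1)).ravel()
    empty = cell_tot == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} all-zero cells before TF-IDF")
        adata = adata[~empty].copy()
        X = sp.csr_matrix(adata.X, dtype=float)
        cell_tot = np.asarray(X.sum(axis=1)).ravel()
    win_count = np.asarray((X > 0).sum(axis=0)).ravel()
    if (win_count == 0).any():
        raise ValueError("all-zero windows present; run filter_windows first")
    idf = X.shape[0] / win_count
    tf = sp.diags(1.0 / cell_tot) @ X
    weighted = tf @ sp.diags(idf)
    weighted.data = np.log1p(scale * weighted.data)
    out = adata.copy()
    out.X = weighted.tocsr()
    return out


def lsa_reduce(adata: ad.AnnData, n_components: int = 40, seed: int = 0) -> np.ndarray:
    """Truncated SVD embedding (cells x n_components), stored in obsm too."""
    n_components = min(n_components, min(adata.shape) - 1)
    svd = TruncatedSVD(n_components=n_components, random_state=seed, algorithm="randomized")
    emb = svd.fit_transform(sp.csr_matrix(adata.X, dtype=float))
    adata.obsm["X_lsa"] = emb
    adata.uns["lsa_explained_variance_ratio"] = svd.explained_variance_ratio_
    return emb


def knn_graph(embedding: np.ndarray, k: int = 15, drop_first_component: bool = True) -> igraph.Graph:
    """KNN graph on components 2..D with shared-neighbor Jaccard edge weights."""
    if k >= len(embedding):
        raise ValueError("k must be smaller than the number of cells")
    emb = embedding[:, 1:] if drop_first_component else embedding
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, neigh = nn.kneighbors(emb)
    n = len(emb)
    neighbor_sets = [set(row) | {i} for i, row in enumerate(neigh)]
    edges, weights = [], []
    seen = set()
    for i, row in enumerate(neigh):
        for j in row:
            j = int(j)
            if i == j or (min(i, j), max(i, j)) in seen:
                continue
            seen.add((min(i, j), max(i, j)))
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            edges.append((i, j))
            weights.append(inter / union)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def louvain_cluster(graph: igraph.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Modularity community labels (Leiden optimizer, fixed seed)."""
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def retain_clusters(labels: np.ndarray, min_cells: int = 50) -> np.ndarray:
    """Mark clusters with <= min_cells cells as unassigned (-1)."""
    labels = np.asarray(labels).copy()
    counts = pd.Series(labels).value_counts()
    small = set(counts.index[counts <= min_cells])
    labels[np.isin(labels, list(small))] = -1
    return labels


def cluster_cells(
    adata: ad.AnnData,
    n_components: int = 40,
    k: int = 15,
    resolution: float = 1.0,
    min_cells: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """filter -> TF-IDF -> SVD -> KNN -> modularity -> size filter."""
    filtered = filter_windows(adata)
    weighted = log_tfidf(filtered)
    emb = lsa_reduce(weighted, n_components=n_components, seed=seed)
    graph = knn_graph(emb, k=k)
    labels = louvain_cluster(graph, resolution=resolution, seed=seed)
    labels = retain_clusters(labels, min_cells=min_cells)
    if len(labels) == adata.n_obs:
        adata.obs["cluster"] = labels
    else:  # TF-IDF may have dropped empty cells
        kept = weighted.obs_names
        adata.obs["cluster"] = pd.Series(labels, index=kept).reindex(adata.obs_names, fill_value=-1).astype(int)
    return labels
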