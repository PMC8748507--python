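"""Genebody-seeded co-accessibility networks and gene activities.

The peak-by-cell matrix is augmented with one genebody row per gene (sum of
all peaks inside the genebody, anchored at a 300 bp window around the TSS:
[TSS-200, TSS+100) on '+', mirrored on '-').  Cells are aggregated over
KNN neighborhoods in the LSA embedding to de-sparsify.  Within overlapping
500 kb genomic windows, a graphical lasso with a distance-proportional
off-diagonal penalty estimates a sparse precision matrix; partial
correlations become co-accessibility scores, averaged across windows, and
edges at score >= 0.1 within the 250 kb distance constraint form the
regulatory network.  Gene activity sums the genebody signal and its linked
peaks, normalized per cell to counts-per-10,000.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

ANCHOR_UP = 200    # bp upstream of the TSS
ANCHOR_DOWN = 100  # bp downstream


def gene_anchor(tss: int, strand: str) -> tuple[int, int]:
    """300 bp anchor interval of a gene ([TSS-200, TSS+100) on '+')."""
    if strand == "+":
        return tss - ANCHOR_UP, tss + ANCHOR_DOWN
    return tss - ANCHOR_DOWN, tss + ANCHOR_UP


def genebody_accessibility(
    X, peak_table: pd.DataFrame, genes: pd.DataFrame
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Append per-gene genebody rows to a cells-x-peaks matrix.

    Returns (cells x (peaks + genes) matrix, node table with columns chrom,
    start, end, node_id, kind['peak'|'gene']).  A gene overlapping no peak
    keeps a zero row.
    """
    X = sp.csr_matrix(X)
    peak_table = peak_table.reset_index(drop=True)
    gene_cols = []
    anchors = []
    for _, g in genes.iterrows():
        inside = (
            (peak_table["chrom"] == g.chrom)
            & (peak_table["start"] < g.end)
            & (peak_table["end"] > g.start)
        )
        idx = np.flatnonzero(inside.values)
        col = X[:, idx].sum(axis=1) if len(idx) else np.zeros((X.shape[0], 1))
        gene_cols.append(np.asarray(col).ravel())
        a_s, a_e = gene_anchor(int(g.tss), g.strand)
        anchors.append((g.chrom, a_s, a_e, g.gene_id, "gene"))
    G = sp.csr_matrix(np.column_stack(gene_cols)) if gene_cols else sp.csr_matrix((X.shape[0], 0))
    combined = sp.hstack([X, G]).tocsr()
    peak_nodes = peak_table[["chrom", "start", "end"]].copy()
    peak_nodes["node_id"] = peak_table["peak_id"].values
    peak_nodes["kind"] = "peak"
    nodes = pd.concat([peak_nodes, pd.DataFrame(anchors, columns=["chrom", "start", "end", "node_id", "kind"])],
                      ignore_index=True)
    return combined, nodes


def aggregate_cells(
    X, embedding: np.ndarray, k: int = 30, n_aggregates: int = 100,
    max_shared: float = 0.9, seed: int = 0,
) -> sp.csr_matrix:
    """Sum counts over KNN neighborhoods of sampled seed cells.

    Seeds are drawn without replacement; each aggregate is the seed plus its
    k-1 nearest neighbors in the embedding; aggregates sharing more than
    ``max_shared`` of their members with an accepted aggregate are dropped.
    """
    X = sp.csr_matrix(X)
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of cells")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, neigh = nn.kneighbors(embedding)
    seeds = rng.permutation(n)
    accepted: list[np.ndarray] = []
    member_sets: list[set] = []
    for s in seeds:
        members = neigh[s]
        mset = set(members.tolist())
        if any(len(mset & prev) > max_shared * k for prev in member_sets):
            continue
        accepted.append(members)
        member_sets.append(mset)
        if len(accepted) >= n_aggregates:
            break
    rows = np.vstack([np.asarray(X[m].sum(axis=0)).ravel() for m in accepted])
    return sp.csr_matrix(rows)


# ---------------------------------------------------------------------------
# graphical lasso with element-wise penalties
# ---------------------------------------------------------------------------

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _glasso_kernel(S, rho, tol, max_iter):  # pragma: no cover - numba
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    converged = False
    for _ in range(max_iter):
        delta_w = 0.0
        for j in range(p):
            # lasso on the j-th column given W11 (W without row/col j)
            beta = np.zeros(p - 1)
            s12 = np.empty(p - 1)
            r12 = np.empty(p - 1)
            idx = np.empty(p - 1, dtype=np.int64)
            t = 0
            for i in range(p):
                if i != j:
                    idx[t] = i
                    s12[t] = S[i, j]
                    r12[t] = rho[i, j]
                    beta[t] = B[i, j]
                    t += 1
            for _ in range(100):
                maxd = 0.0
                for kk in range(p - 1):
                    grad_k = 0.0
                    for ll in range(p - 1):
                        if ll != kk:
                            grad_k += W[idx[kk], idx[ll]] * beta[ll]
                    resid = s12[kk] - grad_k
                    wkk = W[idx[kk], idx[kk]]
                    if resid > r12[kk]:
                        bnew = (resid - r12[kk]) / wkk
                    elif resid < -r12[kk]:
                        bnew = (resid + r12[kk]) / wkk
                    else:
                        bnew = 0.0
                    d = abs(bnew - beta[kk])
                    if d > maxd:
                        maxd = d
                    beta[kk] = bnew
                if maxd < tol * 0.1:
                    break
            for kk in range(p - 1):
                B[idx[kk], j] = beta[kk]
            for kk in range(p - 1):
                w_new = 0.0
                for ll in range(p - 1):
                    w_new += W[idx[kk], idx[ll]] * beta[ll]
                d = abs(W[idx[kk], j] - w_new)
                if d > delta_w:
                    delta_w = d
                W[idx[kk], j] = w_new
                W[j, idx[kk]] = w_new
        if delta_w < tol:
            converged = True
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        denom = W[j, j]
        for i in range(p):
            if i != j:
                denom -= W[i, j] * B[i, j]
        Theta[j, j] = 1.0 / denom
        for i in range(p):
            if i != j:
                Theta[i, j] = -B[i, j] / denom
    return (Theta + Theta.T) / 2.0, converged


def graphical_lasso(S: np.ndarray, rho: np.ndarray, tol: float = 1e-6, max_iter: int = 200) -> np.ndarray:
    """Sparse precision matrix under an element-wise L1 penalty.

    Block coordinate descent (one lasso sub-problem per column) on the
    covariance estimate W; the penalty matrix ``rho`` has zero diagonal.
    Returns the precision matrix Theta.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    rho = np.ascontiguousarray(rho, dtype=np.float64)
    theta, converged = _glasso_kernel(S, rho, float(tol), int(max_iter))
    if not converged:
        raise RuntimeError("graphical lasso failed to converge")
    return theta


def partial_correlations(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def coaccessibility(
    agg: sp.csr_matrix,
    nodes: pd.DataFrame,
    window: int = 500_000,
    step: int = 250_000,
    constraint: int = 250_000,
    penalty_scale: float = 0.25,
    score_cutoff: float = 0.1,
    min_aggregates: int = 10,
) -> pd.DataFrame:
    """Distance-penalized co-accessibility network over genomic windows.

    Within each 500 kb window (step 250 kb) node vectors are log-scaled and
    standardized; the graphical lasso runs with off-diagonal penalty
    ``penalty_scale * d_ij / constraint`` (pairs beyond the constraint get
    an effectively infinite penalty and can never form edges).  Scores for
    pairs seen in several windows are averaged; edges with score >=
    ``score_cutoff`` are returned as (node_a, node_b, score, distance).
    """
    if agg.shape[0] < min_aggregates:
        raise ValueError(f"need at least {min_aggregates} aggregates")
    A = np.log1p(np.asarray(agg.todense(), dtype=float))
    nodes = nodes.reset_index(drop=True)
    mid = ((nodes["start"] + nodes["end"]) // 2).values
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for chrom, sub in nodes.groupby("chrom", sort=True):
        cidx = sub.index.values
        cmid = mid[cidx]
        lo, hi = cmid.min(), cmid.max()
        start0 = (lo // step) * step
        for w0 in range(int(start0), int(hi) + 1, step):
            inw = cidx[(cmid >= w0) & (cmid < w0 + window)]
            if len(inw) < 2:
                continue
            D = A[:, inw]
            sd = D.std(axis=0)
            keep = sd > 0
            inw = inw[keep]
            if len(inw) < 2:
                continue
            D = (D[:, keep] - D[:, keep].mean(axis=0)) / sd[keep]
            S = np.corrcoef(D, rowvar=False)
            dmat = np.abs(mid[inw][:, None] - mid[inw][None, :])
            rho = penalty_scale * dmat / constraint
            rho[dmat > constraint] = 1e6
            np.fill_diagonal(rho, 0.0)
            try:
                theta = graphical_lasso(S, rho)
            except RuntimeError:
                warnings.warn(f"graphical lasso did not converge in window {chrom}:{w0}; skipped")
                continue
            pc = partial_correlations(theta)
            for a in range(len(inw)):
                for b in range(a + 1, len(inw)):
                    if dmat[a, b] > constraint:
                        continue
                    key = (int(min(inw[a], inw[b])), int(max(inw[a], inw[b])))
                    sums[key] = sums.get(key, 0.0) + pc[a, b]
                    counts[key] = counts.get(key, 0) + 1
    rows = []
    for (a, b), total in sums.items():
        score = total / counts[(a, b)]
        if score >= score_cutoff:
            rows.append(
                {
                    "node_a": nodes.loc[a, "node_id"],
                    "node_b": nodes.loc[b, "node_id"],
                    "score": score,
                    "distance": int(abs(mid[a] - mid[b])),
                }
            )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score", "distance"])


def gene_activity(
    edges: pd.DataFrame,
    combined,
    nodes: pd.DataFrame,
    score_cutoff: float = 0.1,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Per-gene, per-cell activity: genebody signal plus linked-peak counts.

    Peaks connected to a gene's anchor with score >= cutoff contribute their
    counts; the resulting gene-by-cell matrix is normalized so each cell
    sums to ``scale`` (counts-per-10,000).
    """
    combined = sp.csr_matrix(combined)
    nodes = nodes.reset_index(drop=True)
    col_of = {nid: i for i, nid in enumerate(nodes["node_id"])}
    gene_ids = nodes.loc[nodes["kind"] == "gene", "node_id"].tolist()
    links: dict[str, set[str]] = {g: set() for g in gene_ids}
    for _, e in edges.iterrows():
        if e.score < score_cutoff:
            continue
        a, b = e.node_a, e.node_b
        if a in links and b not in links:
            links[a].add(b)
        elif b in links and a not in links:
            links[b].add(a)
    cols = {}
    for g in gene_ids:
        j = [col_of[g]] + [col_of[p] for p in sorted(links[g])]
        cols[g] = np.asarray(combined[:, j].sum(axis=1)).ravel()
    act = pd.DataFrame(cols)
    totals = act.sum(axis=1).replace(0, 1.0)
    return act.div(totals, axis=0) * scale
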