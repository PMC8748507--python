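"""Cell-type-specific peak scoring.

From a peak-by-cell matrix and cluster/type labels: keep "high quality"
peaks (accessible in >5% of the cells of some cluster), build the
peak-by-type accessible-cell proportion matrix, pick high-variable peaks by
a vst-style standardized variance, scale each type's proportions by its
median per-cell fragment count, and rank (peak, type) pairs by the squared
Jensen-Shannon specificity times the scaled proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------

def merge_master_peaks(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of per-cluster peak calls: overlapping or adjacent intervals merged."""
    df = pd.concat(peak_sets, ignore_index=True)[["chrom", "start", "end"]]
    if (df["end"] <= df["start"]).any():
        raise ValueError("malformed interval: end <= start")
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# peak selection
# ---------------------------------------------------------------------------

def select_high_quality_peaks(adata: ad.AnnData, labels: pd.Series) -> pd.Index:
    """Peaks accessible in strictly more than 5% of the cells of any cluster."""
    X = sp.csr_matrix(adata.X)
    keep = np.zeros(adata.n_vars, dtype=bool)
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    for lab, idx in labels.groupby(labels).groups.items():
        cells = adata.obs_names.get_indexer(idx)
        if len(cells) == 0:
            raise ValueError(f"empty cluster {lab}")
        frac = np.asarray((X[cells] > 0).sum(axis=0)).ravel() / len(cells)
        keep |= frac > 0.05
    return adata.var_names[keep]


def proportion_matrix(
    adata: ad.AnnData, labels: pd.Series, peaks: pd.Index | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Peak-by-type accessible-cell proportions plus per-type scaling factors.

    The scaling factor of a type is the median total fragment (count) number
    of its cells, as in the normalized proportion matrix used for
    specificity scoring.
    """
    if peaks is not None:
        adata = adata[:, peaks]
    X = sp.csr_matrix(adata.X)
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    depth = np.asarray(X.sum(axis=1)).ravel()
    cols, scales = {}, {}
    for lab, idx in sorted(labels.groupby(labels).groups.items(), key=lambda kv: str(kv[0])):
        cells = adata.obs_names.get_indexer(idx)
        cols[lab] = np.asarray((X[cells] > 0).sum(axis=0)).ravel() / len(cells)
        scales[lab] = float(np.median(depth[cells]))
    prop = pd.DataFrame(cols, index=adata.var_names)
    return prop, pd.Series(scales)


def standardized_variance(mat: pd.DataFrame, span: float = 0.3) -> pd.Series:
    """vst-style standardized variance of each row across columns.

    A loess trend of log10(variance) on log10(mean) gives each row an
    expected SD; values are standardized against it, clipped at sqrt(n
    columns), and the variance of the clipped values is returned.
    """
    X = mat.values.astype(float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 columns")
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    out = np.zeros(len(X))
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 3:
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        fit = lowess(lv, lm, frac=span, return_sorted=True)
        exp_var = 10 ** np.interp(np.log10(np.maximum(mean, 1e-300)), fit[:, 0], fit[:, 1])
    else:
        exp_var = np.full(len(X), max(var.mean(), 1e-12))
    exp_sd = np.sqrt(np.maximum(exp_var, 1e-300))
    clip = np.sqrt(n)
    Z = np.clip((X - mean[:, None]) / exp_sd[:, None], -clip, clip)
    out = Z.var(axis=1, ddof=1)
    out[~np.isfinite(out)] = 0.0
    return pd.Series(out, index=mat.index)


def select_variable_peaks(prop: pd.DataFrame, n: int = 50_000, span: float = 0.3) -> pd.Index:
    """Top-n peaks by standardized variance across cell types."""
    if prop.shape[1] < 2:
        raise ValueError("variable-peak selection needs at least 2 cell types")
    sv = standardized_variance(prop, span=span)
    if n >= len(sv):
        if n > len(sv):
            warnings.warn(f"requested {n} variable peaks but only {len(sv)} available")
        return prop.index
    order = np.lexsort((np.arange(len(sv)), -sv.values))
    return prop.index[order[:n]]


# ---------------------------------------------------------------------------
# Jensen-Shannon specificity
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy, base 2, with 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=axis)


def js_divergence_onehot(q: np.ndarray) -> np.ndarray:
    """Base-2 Jensen-Shannon divergence of each row of q against each one-hot.

    Returns an array of shape (rows, types); JSD(q, e_t) = H((q + e_t)/2) -
    H(q)/2, since the entropy of a one-hot distribution is 0.  Bounded in
    [0, 1] with base-2 logs.
    """
    q = np.asarray(q, dtype=float)
    n, k = q.shape
    hq = _entropy2(q)
    out = np.empty((n, k))
    for t in range(k):
        m = q / 2.0
        m[:, t] += 0.5
        out[:, t] = _entropy2(m) - hq / 2.0
    return np.clip(out, 0.0, 1.0)


@dataclass
class SpecificityTable:
    """Per (peak, type) specificity components and the final ranking inputs."""

    specificity: pd.DataFrame   # s = 1 - sqrt(JSD), in [0, 1]
    scaled: pd.DataFrame        # proportion x per-type scaling factor
    final: pd.DataFrame         # s^2 * scaled


def js_specificity(prop: pd.DataFrame, scales: pd.Series) -> SpecificityTable:
    """Jensen-Shannon specificity of the scaled proportion matrix.

    Rows whose scaled values are all zero carry no distributional
    information and are excluded.
    """
    scaled = prop * scales.reindex(prop.columns).values[None, :]
    rowsum = scaled.sum(axis=1)
    keep = rowsum > 0
    scaled = scaled.loc[keep]
    q = scaled.values / scaled.values.sum(axis=1, keepdims=True)
    jsd = js_divergence_onehot(q)
    s = 1.0 - np.sqrt(jsd)
    spec = pd.DataFrame(s, index=scaled.index, columns=scaled.columns)
    final = spec**2 * scaled
    return SpecificityTable(specificity=spec, scaled=scaled, final=final)


def select_specific_peaks(
    table: SpecificityTable, top_n: int = 20_000
) -> pd.DataFrame:
    """Top (peak, type) returns by final score, deduplicated by peak.

    Each retained peak is assigned to its best-scoring type; exact ties go
    to the lexicographically first type.  Returns a DataFrame (peak_id,
    cell_type, final_score) with at most ``top_n`` unique peaks.
    """
    final = table.final
    long = final.stack().rename("final_score").reset_index()
    long.columns = ["peak_id", "cell_type", "final_score"]
    long = long.sort_values(
        ["final_score", "peak_id", "cell_type"], ascending=[False, True, True], kind="mergesort"
    )
    top = long.head(top_n)
    top = top.drop_duplicates("peak_id", keep="first").reset_index(drop=True)
    return top
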