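"""Mapping bulk tumor samples onto candidate cells of origin.

Three independent statistics connect a bulk tumor ATAC profile to the
normal cell types:

1. peak overlap: the fraction of tumor peaks intersecting a cell type's
   specific peaks, tested against random draws from the pooled specific
   peaks (binomial tail at the permutation-expected fraction, BH-adjusted);
2. correlation: Pearson correlation of log-CPM + quantile normalized
   accessibility over shared variable peaks, averaged within cell-type
   groups, with a 2-cut hierarchical clustering of the correlation rows
   splitting the cohort into origin subgroups;
3. similarity scores: one-vs-rest L1-regularized binomial models trained on
   a pseudo-bulk panel with a fixed per-class offset log(f / (1 - f)) and
   applied to tumors with offset 0.

A negative-binomial exact test (library-normalized counts, common
method-of-moments dispersion, conditional two-group comparison) calls
differential peaks between tumor subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import expit
from scipy.stats import binom, nbinom, rankdata
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# peak overlap
# ---------------------------------------------------------------------------

def _interval_hits(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: intersects >= 1 subject interval."""
    hit = np.zeros(len(query), dtype=bool)
    qs = query.reset_index(drop=True)
    for chrom, sub in subject.groupby("chrom", sort=False):
        idx = np.flatnonzero(qs["chrom"].values == chrom)
        if not len(idx):
            continue
        order = np.argsort(sub["start"].values)
        ss = sub["start"].values[order]
        se = sub["end"].values[order]
        # merge subject intervals for a clean searchsorted test
        ms, me = [ss[0]], [se[0]]
        for s, e in zip(ss[1:], se[1:]):
            if s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        ms, me = np.array(ms), np.array(me)
        q_start = qs["start"].values[idx]
        q_end = qs["end"].values[idx]
        j = np.searchsorted(me, q_start, side="right")
        ok = j < len(ms)
        jj = np.minimum(j, len(ms) - 1)
        hit[idx] = ok & (ms[jj] < q_end)
    return hit


def overlap_fraction(cancer_peaks: pd.DataFrame, celltype_peaks: pd.DataFrame) -> float:
    """Fraction of cancer peaks intersecting at least one cell-type peak."""
    if len(cancer_peaks) == 0:
        raise ValueError("empty cancer peak set")
    return float(_interval_hits(cancer_peaks, celltype_peaks).mean())


def permutation_overlap_test(
    cancer_sets: dict[str, pd.DataFrame],
    celltype_sets: dict[str, pd.DataFrame],
    pooled: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs permutation-expected overlap for every (cancer, type) pair.

    For each pair, ``n_perm`` random same-size draws from the pooled
    specific peaks give the expected overlap fraction; the one-sided p is
    the binomial upper tail P(X >= observed | n cancer peaks, expected
    fraction), BH-adjusted across pairs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = pooled.reset_index(drop=True)
    rows = []
    for cname, cpeaks in cancer_sets.items():
        cpeaks = cpeaks.reset_index(drop=True)
        for tname, tpeaks in celltype_sets.items():
            obs_frac = overlap_fraction(cpeaks, tpeaks)
            n_cancer = len(cpeaks)
            obs_count = int(round(obs_frac * n_cancer))
            fracs = np.empty(n_perm)
            for b in range(n_perm):
                draw = pooled.iloc[rng.choice(len(pooled), size=len(tpeaks), replace=False)]
                fracs[b] = _interval_hits(cpeaks, draw).mean()
            expected = float(fracs.mean())
            p = float(binom.sf(obs_count - 1, n_cancer, min(max(expected, 1e-12), 1 - 1e-12)))
            rows.append(
                {
                    "cancer": cname,
                    "cell_type": tname,
                    "observed_fraction": obs_frac,
                    "expected_fraction": expected,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def logcpm_normalize(counts: pd.DataFrame, prior: float = 5.0) -> pd.DataFrame:
    """log2 counts-per-million with a library-size-scaled prior count.

    With library sizes L_j and p_j = prior * L_j / mean(L):
    value = log2((c + p_j) / (L_j + 2 p_j) * 1e6).
    """
    L = counts.sum(axis=0).values.astype(float)
    if (L <= 0).any():
        raise ValueError("zero library size")
    p = prior * L / L.mean()
    vals = np.log2((counts.values + p[None, :]) / (L + 2 * p)[None, :] * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the cross-column mean quantile profile.

    Ties within a column receive the mean of their quantile values
    (average ranks interpolated into the reference distribution).
    """
    X = mat.values.astype(float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, X.shape[0] + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def normalize_counts(counts: pd.DataFrame, prior: float = 5.0) -> pd.DataFrame:
    """log-CPM followed by quantile normalization (the bulk ATAC recipe)."""
    return quantile_normalize(logcpm_normalize(counts, prior=prior))


def top_ranked_peaks(normalized: pd.DataFrame, n: int) -> pd.Index:
    """Highest-signal features by mean normalized accessibility."""
    order = np.lexsort((np.arange(len(normalized)), -normalized.mean(axis=1).values))
    return normalized.index[order[: min(n, len(normalized))]]


# ---------------------------------------------------------------------------
# correlation mapping
# ---------------------------------------------------------------------------

def correlate_samples_celltypes(
    tumor: pd.DataFrame,
    reference: pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlation of each tumor sample with each cell-type group.

    Both matrices must already be normalized and restricted to the shared
    (variable) peak set.  Reference columns are averaged within their group
    after correlating.  Hierarchical clustering (correlation distance,
    average linkage, cut at 2) of the correlation rows splits the cohort
    into two origin subgroups.
    """
    shared = tumor.index.intersection(reference.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared peaks")
    T = tumor.loc[shared].values
    R = reference.loc[shared].values
    Tc = T - T.mean(axis=0)
    Rc = R - R.mean(axis=0)
    num = Tc.T @ Rc
    den = np.outer(np.sqrt((Tc**2).sum(axis=0)), np.sqrt((Rc**2).sum(axis=0)))
    corr = pd.DataFrame(num / den, index=tumor.columns, columns=reference.columns)
    if groups:
        grouped = corr.T.groupby(pd.Series(groups).reindex(corr.columns)).mean().T
    else:
        grouped = corr
    if grouped.shape[0] > 2:
        Z = linkage(grouped.values, method="average", metric="correlation")
        split = pd.Series(fcluster(Z, t=2, criterion="maxclust"), index=grouped.index)
    else:
        split = pd.Series(1, index=grouped.index)
    return grouped, split


# ---------------------------------------------------------------------------
# pseudo-bulk similarity models
# ---------------------------------------------------------------------------

def build_pseudobulk_panel(
    adata: ad.AnnData,
    labels: pd.Series,
    cells_per_rep: int = 50,
    reps: int = 20,
    seed: int = 0,
    prior: float = 5.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Pseudo-bulk reference panel: per type, ``reps`` sums of sampled cells.

    Types with fewer than ``cells_per_rep`` cells are sampled with
    replacement (with a warning).  Returns (normalized panel peaks x
    replicates, replicate type labels, raw panel counts).
    """
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(adata.X)
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    cols, col_labels = {}, {}
    for lab, idx in sorted(labels.groupby(labels).groups.items(), key=lambda kv: str(kv[0])):
        cells = adata.obs_names.get_indexer(idx)
        if len(cells) == 0:
            raise ValueError(f"empty cell type {lab}")
        replace = len(cells) < cells_per_rep
        if replace:
            warnings.warn(f"type {lab} has {len(cells)} < {cells_per_rep} cells; sampling with replacement")
        for r in range(reps):
            pick = rng.choice(cells, size=cells_per_rep, replace=replace)
            name = f"{lab}_rep{r:02d}"
            cols[name] = np.asarray(X[pick].sum(axis=0)).ravel()
            col_labels[name] = lab
    raw = pd.DataFrame(cols, index=adata.var_names)
    panel = normalize_counts(raw, prior=prior)
    return panel, pd.Series(col_labels, name="cell_type"), raw


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard speedup, soft dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _lasso_path_kernel(X, y, offset, lambdas, tol, max_iter):  # pragma: no cover - numba
    n, p = X.shape
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for li in range(len(lambdas)):
        lam = lambdas[li]
        for _ in range(max_iter):
            eta = offset + X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-5)
            z = eta - offset + (y - mu) / w
            beta_old = beta.copy()
            r = z - X @ beta
            for j in range(p):
                xj = X[:, j]
                r += xj * beta[j]
                rho = 0.0
                wx2 = 0.0
                for i in range(n):
                    rho += w[i] * xj[i] * r[i]
                    wx2 += w[i] * xj[i] * xj[i]
                rho /= n
                wx2 /= n
                if rho > lam:
                    beta[j] = (rho - lam) / wx2
                elif rho < -lam:
                    beta[j] = (rho + lam) / wx2
                else:
                    beta[j] = 0.0
                r -= xj * beta[j]
            delta = 0.0
            for j in range(p):
                d = abs(beta[j] - beta_old[j])
                if d > delta:
                    delta = d
            if delta < tol:
                break
        betas[li] = beta
    return betas


def _logistic_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Coordinate-descent L1 logistic regression (no intercept, fixed offset).

    Minimizes mean negative log-likelihood + lambda * ||beta||_1 along a
    decreasing lambda path with warm starts.  X should be standardized.
    """
    return _lasso_path_kernel(
        np.ascontiguousarray(X, dtype=np.float64),
        np.asarray(y, dtype=np.float64),
        np.asarray(offset, dtype=np.float64),
        np.asarray(lambdas, dtype=np.float64),
        tol,
        max_iter,
    )


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


@dataclass
class SimilarityModel:
    """One-vs-rest regularized binomial model for one cell type."""

    cell_type: str
    class_fraction: float
    offset: float                 # log(f / (1 - f)), used only in training
    lam: float                    # selected regularization strength
    coef: pd.Series               # over standardized features
    feature_mean: pd.Series
    feature_sd: pd.Series

    def predict(self, mat: pd.DataFrame) -> pd.Series:
        """Similarity scores for columns of a normalized feature matrix
        (prediction uses offset 0)."""
        feats = self.coef.index
        if not feats.isin(mat.index).all():
            raise ValueError("feature mismatch between model and matrix")
        Z = ((mat.loc[feats].T - self.feature_mean.values) / self.feature_sd.values).values
        return pd.Series(expit(Z @ self.coef.values), index=mat.columns)


def train_similarity_models(
    panel: pd.DataFrame,
    labels: pd.Series,
    feature_peaks: pd.Index,
    n_folds: int = 10,
    n_lambda: int = 25,
    lambda_min_ratio: float = 1e-3,
    seed: int = 0,
) -> list[SimilarityModel]:
    """L1 binomial one-vs-rest models with per-class training offsets.

    lambda is chosen per model as the largest value whose ``n_folds``-fold
    cross-validated deviance lies within one standard error of the minimum.
    """
    feature_peaks = pd.Index(feature_peaks).intersection(panel.index)
    mat = panel.loc[feature_peaks]
    Xfull = mat.T.values
    mean = Xfull.mean(axis=0)
    sd = Xfull.std(axis=0)
    sd[sd == 0] = 1.0
    X = (Xfull - mean) / sd
    n = X.shape[0]
    labels = pd.Series(np.asarray(labels), index=panel.columns)
    rng = np.random.default_rng(seed)

    models = []
    for lab in sorted(labels.unique(), key=str):
        y = (labels.values == lab).astype(float)
        if y.sum() < 2:
            raise ValueError(f"cell type {lab} has fewer than 2 replicates")
        f = float(y.mean())
        off_val = float(np.log(f / (1 - f)))
        offset = np.full(n, off_val)

        lam_max = np.max(np.abs(X.T @ (y - f))) / n
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

        # stratified folds
        folds = np.empty(n, dtype=int)
        for cls in (0.0, 1.0):
            idx = np.flatnonzero(y == cls)
            folds[idx[rng.permutation(len(idx))]] = np.arange(len(idx)) % n_folds
        cv_dev = np.zeros((n_folds, len(lambdas)))
        for k in range(n_folds):
            tr, va = folds != k, folds == k
            betas = _logistic_lasso_path(X[tr], y[tr], offset[tr], lambdas)
            for li in range(len(lambdas)):
                mu = expit(offset[va] + X[va] @ betas[li])
                cv_dev[k, li] = _binomial_deviance(y[va], mu) / va.sum()
        cvm = cv_dev.mean(axis=0)
        cvse = cv_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmin(cvm))
        admissible = np.flatnonzero(cvm <= cvm[best] + cvse[best])
        li_sel = int(admissible.min())  # lambdas decrease: smallest index = largest lambda

        beta = _logistic_lasso_path(X, y, offset, lambdas[: li_sel + 1])[-1]
        models.append(
            SimilarityModel(
                cell_type=str(lab),
                class_fraction=f,
                offset=off_val,
                lam=float(lambdas[li_sel]),
                coef=pd.Series(beta, index=feature_peaks),
                feature_mean=pd.Series(mean, index=feature_peaks),
                feature_sd=pd.Series(sd, index=feature_peaks),
            )
        )
    return models


def predict_similarity(models: list[SimilarityModel], tumor: pd.DataFrame) -> pd.DataFrame:
    """Similarity scores (samples x types) at offset 0, plus per-sample argmax."""
    scores = pd.DataFrame({m.cell_type: m.predict(tumor) for m in models})
    scores["argmax"] = scores.idxmax(axis=1)
    return scores


# ---------------------------------------------------------------------------
# negative-binomial exact differential test
# ---------------------------------------------------------------------------

def _effective_library_sizes(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios effective library sizes (composition-robust).

    Each sample's scale is the median ratio of its counts to the per-feature
    geometric mean, computed over features expressed in every sample; this
    keeps a minority of strongly changed features from dragging every other
    feature's normalized value (the classic composition bias of raw column
    totals).  Falls back to column totals when no feature qualifies.
    """
    totals = counts.sum(axis=0).astype(float)
    pos = (counts > 0).all(axis=1)
    if pos.sum() < 10:
        return totals
    logc = np.log(counts[pos].astype(float))
    ref = logc.mean(axis=1)
    ratios = np.exp(np.median(logc - ref[:, None], axis=0))
    sizes = totals.mean() * ratios / ratios.mean()
    return sizes


def _common_dispersion(norm_counts: np.ndarray, groups: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion across features.

    Within-group variances estimate mu + phi mu^2; phi is the pooled ratio
    sum(s^2 - mu) / sum(mu^2), floored at 0.
    """
    num, den = 0.0, 0.0
    for g in np.unique(groups):
        sub = norm_counts[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    return max(0.0, num / den) if den > 0 else 0.0


def _exact_nb_pvalue(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional test of equal means given the total.

    Under H0 the group sums are NB with means n_g * mu and sizes n_g / phi
    (Poisson when phi = 0, making the conditional law binomial).  The
    two-sided p sums the probabilities of all outcomes no more likely than
    the observed one, edgeR's "small-p" convention.
    """
    s = y1 + y2
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi <= 1e-12:
        logp = binom.logpmf(k, s, n1 / (n1 + n2))
    else:
        mu = s / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        logp1 = nbinom.logpmf(k, r1, r1 / (r1 + n1 * mu))
        logp2 = nbinom.logpmf(s - k, r2, r2 / (r2 + n2 * mu))
        logp = logp1 + logp2
        logp -= np.logaddexp.reduce(logp)
    p_obs = logp[y1]
    return float(min(1.0, np.exp(np.logaddexp.reduce(logp[logp <= p_obs + 1e-12]))))


def differential_peaks(
    counts: pd.DataFrame,
    groups: pd.Series,
    lfc_threshold: float = 2.5,
    fdr_threshold: float = 0.05,
    logcpm_threshold: float = 1.0,
    prefilter: bool = False,
) -> pd.DataFrame:
    """NB exact test per feature between two sample groups.

    Counts are scaled to a common library size; a common dispersion is
    estimated by method of moments across all features; each feature's
    group sums are compared by the conditional exact test.  A feature
    passes iff |log2FC| > ``lfc_threshold`` AND BH-FDR < ``fdr_threshold``
    AND average log2-CPM > ``logcpm_threshold``.  With ``prefilter``,
    features with mean < 1 or SD > 10 are removed first.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    levels = sorted(groups.unique(), key=str)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if any((groups == g).sum() < 2 for g in levels):
        raise ValueError("each group needs at least 2 samples")
    if prefilter:
        m = counts.mean(axis=1)
        s = counts.std(axis=1, ddof=1)
        counts = counts.loc[(m >= 1) & (s <= 10)]

    L = _effective_library_sizes(counts.values)
    if (L <= 0).any():
        raise ValueError("zero library size")
    Lbar = L.mean()
    norm = counts.values * (Lbar / L)[None, :]
    gvec = groups.values
    phi = _common_dispersion(norm, gvec)

    g1, g2 = levels
    n1 = int((gvec == g1).sum())
    n2 = int((gvec == g2).sum())
    y1 = np.round(norm[:, gvec == g1].sum(axis=1)).astype(np.int64)
    y2 = np.round(norm[:, gvec == g2].sum(axis=1)).astype(np.int64)

    pvals = np.array([_exact_nb_pvalue(int(a), int(b), n1, n2, phi) for a, b in zip(y1, y2)])
    logfc = np.log2((y1 / n1 + 0.5) / (y2 / n2 + 0.5))
    ave_logcpm = np.log2((y1 + y2) / (n1 + n2) / Lbar * 1e6 + 0.5)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": ave_logcpm,
            "p_value": pvals,
            "FDR": fdr,
        },
        index=counts.index,
    )
    out["significant"] = (
        (np.abs(out["logFC"]) > lfc_threshold)
        & (out["FDR"] < fdr_threshold)
        & (out["logCPM"] > logcpm_threshold)
    )
    out["up_in"] = np.where(out["logFC"] > 0, g1, g2)
    out.attrs["dispersion"] = phi
    out.attrs["groups"] = (g1, g2)
    return out


def differential_gene_sets(diff: pd.DataFrame) -> dict[str, set[str]]:
    """Per-group significant up-feature sets from a differential table."""
    g1, g2 = diff.attrs["groups"]
    sig = diff[diff["significant"]]
    return {
        g1: set(sig.index[sig["logFC"] > 0]),
        g2: set(sig.index[sig["logFC"] < 0]),
    }
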