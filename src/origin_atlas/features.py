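"""Origin-derived feature genes, bulk subgrouping, and CIMP enrichment.

Cell-type feature genes come from the single-cell gene-activity matrix
(pct.1 > 0.5, avg_logFC > 0.5, rank-sum BH p < 0.05 after removing genes
active in fewer than 10 cells).  Tumor-subgroup feature genes come from the
NB differential machinery (|logFC| > 1, FDR < 0.05, logCPM > 5).  Their
per-pair intersection yields the origin-derived feature sets used to
subgroup the expression cohort, and the clinical-label enrichment in the
resulting subgroup is tested by the bootstrap-plus-normal-tail procedure
with an exact hypergeometric oracle alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, mannwhitneyu, norm
from statsmodels.stats.multitest import multipletests

from .origin import differential_peaks


def celltype_feature_genes(
    activity: pd.DataFrame,
    labels: pd.Series,
    min_cells: int = 10,
    pct_threshold: float = 0.5,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    use_rank_test: bool = True,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Marker genes per cell type from a cells-x-genes activity matrix.

    For each type vs the rest: pct.1 is the fraction of the type's cells
    with nonzero activity; avg_logFC = ln((mean_in + 1) / (mean_out + 1));
    a BH-adjusted Wilcoxon rank-sum p < ``p_threshold`` is additionally
    required when ``use_rank_test``.  Genes active in fewer than
    ``min_cells`` cells are removed before testing; types with fewer than
    3 cells are skipped with a warning.
    """
    labels = pd.Series(np.asarray(labels), index=activity.index)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 cell types")
    active_cells = (activity > 0).sum(axis=0)
    act = activity.loc[:, active_cells >= min_cells]

    rows = []
    for lab in sorted(labels.unique(), key=str):
        mask = (labels == lab).values
        if mask.sum() < 3:
            warnings.warn(f"type {lab} has fewer than 3 cells; skipped")
            continue
        sub_in = act.values[mask]
        sub_out = act.values[~mask]
        pct1 = (sub_in > 0).mean(axis=0)
        lfc = np.log((sub_in.mean(axis=0) + 1.0) / (sub_out.mean(axis=0) + 1.0))
        if use_rank_test:
            pvals = mannwhitneyu(sub_in, sub_out, alternative="greater", axis=0).pvalue
            padj = multipletests(pvals, method="fdr_bh")[1]
        else:
            padj = np.zeros(act.shape[1])
        for g, p1, fc, pa in zip(act.columns, pct1, lfc, padj):
            rows.append({"cell_type": lab, "gene_id": g, "pct1": p1, "avg_logFC": fc, "p_adjusted": pa})
    table = pd.DataFrame(rows)
    sig = table[
        (table["pct1"] > pct_threshold)
        & (table["avg_logFC"] > lfc_threshold)
        & (table["p_adjusted"] < p_threshold)
    ]
    sets = {lab: set(sub["gene_id"]) for lab, sub in sig.groupby("cell_type")}
    for lab in sorted(labels.unique(), key=str):
        sets.setdefault(lab, set())
    return sets, table


def subgroup_feature_genes(
    gene_counts: pd.DataFrame,
    groups: pd.Series,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    logcpm_threshold: float = 5.0,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-subgroup up-gene sets via the NB exact differential test."""
    diff = differential_peaks(
        gene_counts, groups,
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
        logcpm_threshold=logcpm_threshold,
    )
    g1, g2 = diff.attrs["groups"]
    sig = diff[diff["significant"]]
    sets = {
        g1: set(sig.index[sig["logFC"] > 0]),
        g2: set(sig.index[sig["logFC"] < 0]),
    }
    return sets, diff


@dataclass
class OriginDerivedFeatures:
    """Named origin-derived gene sets (subgroup name -> genes)."""

    sets: dict[str, set[str]]


def derive_origin_features(
    celltype_sets: dict[str, set[str]],
    subgroup_sets: dict[str, set[str]],
    pairing: dict[str, str],
) -> OriginDerivedFeatures:
    """Intersect each subgroup's feature genes with its paired cell type's.

    ``pairing`` maps subgroup name -> cell type name.  Empty intersections
    warn rather than fail.
    """
    out = {}
    for subgroup, celltype in pairing.items():
        if subgroup not in subgroup_sets:
            raise KeyError(f"unknown subgroup {subgroup}")
        if celltype not in celltype_sets:
            raise KeyError(f"unknown cell type {celltype}")
        inter = subgroup_sets[subgroup] & celltype_sets[celltype]
        if not inter:
            warnings.warn(f"empty origin-derived feature set for {subgroup} x {celltype}")
        out[subgroup] = inter
    return OriginDerivedFeatures(out)


def subgroup_bulk_samples(
    expression: pd.DataFrame,
    features: OriginDerivedFeatures,
    a2_name: str = "a2",
) -> pd.Series:
    """Split expression samples into a1_Like / a2_Like on feature-gene z-scores.

    Samples are hierarchically clustered (correlation distance, average
    linkage, cut at 2) on per-gene z-scores of the pooled feature genes;
    the cluster with the higher mean z over the a2 features is a2_Like.
    """
    genes = sorted(set().union(*features.sets.values()) & set(expression.index))
    if len(genes) < 2:
        raise ValueError("need at least 2 feature genes present in the matrix")
    sub = expression.loc[genes]
    sd = sub.std(axis=1, ddof=0).replace(0, 1.0)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    if z.shape[1] < 2 or np.allclose(z.values.std(axis=1), 0):
        raise ValueError("no 2-cluster structure: samples are identical")
    Z = linkage(z.T.values, method="average", metric="correlation")
    cut = fcluster(Z, t=2, criterion="maxclust")
    a2_genes = sorted(features.sets.get(a2_name, set()) & set(genes))
    means = {c: z.loc[a2_genes, cut == c].values.mean() for c in np.unique(cut)}
    a2_cluster = max(means, key=means.get)
    labels = np.where(cut == a2_cluster, f"{a2_name}_Like", "a1_Like" if a2_name != "a1" else "other_Like")
    return pd.Series(labels, index=expression.columns, name="subgroup")


@dataclass
class EnrichmentResult:
    """Label enrichment of a subgroup: bootstrap normal tail + exact oracle."""

    n_total: int
    n_subgroup: int
    n_labeled: int
    observed: int
    reps: int
    bootstrap_mean: float
    bootstrap_sd: float
    p_normal_tail: float
    p_hypergeometric: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "N": self.n_total, "n": self.n_subgroup, "m": self.n_labeled,
            "observed": self.observed, "reps": self.reps,
            "bootstrap_mean": self.bootstrap_mean, "bootstrap_sd": self.bootstrap_sd,
            "p_normal_tail": self.p_normal_tail, "p_hypergeometric": self.p_hypergeometric,
            "degenerate": self.degenerate,
        }


def cimp_bootstrap_test(
    n_total: int,
    n_subgroup: int,
    n_labeled: int,
    observed: int,
    reps: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Probability of recovering ``observed`` labeled samples in the subgroup.

    Repeatedly draw ``n_subgroup`` of ``n_total`` samples without
    replacement, count how many of the ``n_labeled`` labeled samples are
    included, fit a normal (sample mean, sample SD) to the counts, and
    report the upper-tail probability at the observed count.  The exact
    hypergeometric P(X >= observed) is computed alongside as an oracle.
    """
    if not (0 <= n_labeled <= n_total and 0 <= n_subgroup <= n_total):
        raise ValueError("inconsistent cohort geometry")
    if observed > n_labeled:
        raise ValueError("observed exceeds the number of labeled samples")
    rng = np.random.default_rng(seed)
    counts = rng.hypergeometric(n_labeled, n_total - n_labeled, n_subgroup, size=reps)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        p_norm = 0.0 if observed > mean else 1.0
    else:
        p_norm = float(norm.sf(observed, loc=mean, scale=sd))
    p_exact = float(hypergeom.sf(observed - 1, n_total, n_labeled, n_subgroup))
    return EnrichmentResult(
        n_total=n_total, n_subgroup=n_subgroup, n_labeled=n_labeled,
        observed=observed, reps=reps,
        bootstrap_mean=mean, bootstrap_sd=sd,
        p_normal_tail=p_norm, p_hypergeometric=p_exact,
        degenerate=degenerate,
    )
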