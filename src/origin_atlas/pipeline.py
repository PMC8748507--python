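"""End-to-end orchestration of the cell-of-origin tracing pipeline.

Stages run in dependency order inside a write-once run directory:

    simulate -> qc -> cluster -> peaks -> map_origin -> network
             -> features -> subtype -> enrichment

Each stage derives its own RNG seed deterministically from the global seed
and the stage name, writes plain-text outputs, and is skipped on re-run if
its outputs already exist (resume semantics).  A manifest records
parameters, per-stage seeds, and SHA-256 checksums of every output, so two
runs with the same config are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import coaccess, io, lsa, origin, qc, specificity as spc
from . import features as ft
from .config import SimulationConfig
from .genome import ToyGenome, toy_genome
from .simulate import (
    peak_layout,
    simulate_bulk_tumors,
    simulate_expression,
    simulate_fragments,
    simulate_peak_matrix,
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters, with the study defaults."""

    outdir: str = "run"
    seed: int = 0
    sim: SimulationConfig = None  # seeded from `seed` when omitted
    genome_chroms: int = 2
    genome_chrom_size: int = 25_000_000
    genome_genes: int = 200

    window: int = 5000
    svd_components: int = 40
    knn_k: int = 15
    resolution: float = 1.0
    min_cluster_cells: int = 50

    variable_n: int = 50_000
    top_specific: int | None = None  # default: K x specific_peaks_per_type

    n_perm: int = 1000
    panel_cells: int = 50
    panel_reps: int = 20
    cv_folds: int = 10

    agg_k: int = 30
    n_aggregates: int = 100
    coaccess_window: int = 500_000
    coaccess_step: int = 250_000
    coaccess_constraint: int = 250_000
    edge_cutoff: float = 0.1

    diff_lfc: float = 2.5
    diff_fdr: float = 0.05
    diff_logcpm: float = 1.0
    gene_lfc: float = 1.0
    gene_logcpm: float = 5.0

    bootstrap_reps: int = 10_000

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimulationConfig(seed=stage_seed(self.seed, "simulate"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


STAGE_OUTPUTS = {
    "simulate": [
        "genome_chroms.tsv", "genes.tsv", "fragments.tsv", "barcode_labels.tsv",
        "peaks.bed", "peakmatrix.mtx", "peakmatrix.features.tsv", "peakmatrix.barcodes.tsv",
        "bulk_counts.tsv", "bulk_origins.tsv", "bulk_peaks.bed",
        "expression.tsv", "expression_meta.tsv", "markers.json",
    ],
    "qc": ["qc_table.tsv", "qc_summary.json", "retained_barcodes.tsv"],
    "cluster": ["cluster_labels.tsv"],
    "peaks": ["hq_peaks.tsv", "specific_peaks.tsv", "specificity.tsv"],
    "map_origin": [
        "correlation.tsv", "subgroups_atac.tsv", "similarity.tsv",
        "overlap_test.tsv", "differential_peaks.tsv", "pairing.json",
    ],
    "network": ["edges.tsv", "gene_activity.tsv"],
    "features": ["celltype_features.json", "subgroup_features.json", "origin_features.json"],
    "subtype": ["sample_subgroups.tsv"],
    "enrichment": ["enrichment.json"],
}


def _done(run: Path, stage: str) -> bool:
    return all((run / f).exists() for f in STAGE_OUTPUTS[stage])


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, resume: bool = True) -> dict:
    """Execute all stages; returns a summary dict (also in the manifest)."""
    run = Path(config.outdir)
    run.mkdir(parents=True, exist_ok=True)
    cfg = config
    sim = cfg.sim
    genome = toy_genome(cfg.genome_chroms, cfg.genome_chrom_size, cfg.genome_genes,
                        seed=stage_seed(cfg.seed, "genome"))

    # ---------------- simulate ----------------
    if not (resume and _done(run, "simulate")):
        frags, labels = simulate_fragments(genome, sim)
        adata = simulate_peak_matrix(genome, sim)
        bulk, origins, bulk_peaks = simulate_bulk_tumors(adata, genome, sim)
        expr, meta = simulate_expression(genome, sim)
        _, markers = peak_layout(genome, sim)
        pd.DataFrame(genome.chrom_sizes.items(), columns=["chrom", "size"]).to_csv(
            run / "genome_chroms.tsv", sep="\t", index=False)
        genome.genes.to_csv(run / "genes.tsv", sep="\t", index=False)
        io.write_fragments(frags, run / "fragments.tsv")
        labels.to_csv(run / "barcode_labels.tsv", sep="\t", index=False)
        io.write_bed(adata.var.reset_index(), run / "peaks.bed", extra=["peak_id", "label"])
        io.write_anndata_mtx(adata, run / "peakmatrix")
        bulk.to_csv(run / "bulk_counts.tsv", sep="\t")
        origins.rename_axis("sample").to_csv(run / "bulk_origins.tsv", sep="\t")
        io.write_bed(bulk_peaks, run / "bulk_peaks.bed", extra=["peak_id", "label"])
        expr.to_csv(run / "expression.tsv", sep="\t")
        meta.to_csv(run / "expression_meta.tsv", sep="\t")
        _write_json({k: sorted(v) for k, v in markers.items()}, run / "markers.json")

    frags = io.read_fragments(run / "fragments.tsv")
    labels = pd.read_csv(run / "barcode_labels.tsv", sep="\t")
    M, feats, bcs = io.read_matrix(run / "peakmatrix")
    peaks_bed = io.read_bed(run / "peaks.bed").rename(columns={"name": "peak_id", "score": "label"})
    import anndata as ad
    adata = ad.AnnData(
        X=M.T.tocsr(),
        obs=labels.set_index("barcode").loc[bcs][["cell_type"]],
        var=peaks_bed.set_index("peak_id").loc[feats],
    )
    bulk = pd.read_csv(run / "bulk_counts.tsv", sep="\t", index_col=0)
    origins = pd.read_csv(run / "bulk_origins.tsv", sep="\t", index_col=0)["origin"]
    expr = pd.read_csv(run / "expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(run / "expression_meta.tsv", sep="\t", index_col=0)

    # ---------------- qc ----------------
    if not (resume and _done(run, "qc")):
        table = qc.barcode_qc_table(frags, genome)
        cutoffs = qc.fit_qc_cutoffs(table, seed=stage_seed(cfg.seed, "qc"))
        retained, failures = qc.filter_barcodes(table, cutoffs)
        table.to_csv(run / "qc_table.tsv", sep="\t")
        _write_json(
            {
                "cutoffs": dataclasses.asdict(cutoffs),
                "failures": failures,
                "n_retained": len(retained),
                "n_total": len(table),
            },
            run / "qc_summary.json",
        )
        pd.Series(retained).to_csv(run / "retained_barcodes.tsv", sep="\t", header=False, index=False)
    retained = pd.Index(pd.read_csv(run / "retained_barcodes.tsv", sep="\t", header=None)[0])

    # ---------------- cluster ----------------
    if not (resume and _done(run, "cluster")):
        wm = lsa.build_window_matrix(frags, genome, window=cfg.window, barcodes=retained)
        clust = lsa.cluster_cells(
            wm, n_components=cfg.svd_components, k=cfg.knn_k,
            resolution=cfg.resolution, min_cells=cfg.min_cluster_cells,
            seed=stage_seed(cfg.seed, "cluster"),
        )
        pd.DataFrame({"barcode": wm.obs_names, "cluster": clust}).to_csv(
            run / "cluster_labels.tsv", sep="\t", index=False)
    clusters = pd.read_csv(run / "cluster_labels.tsv", sep="\t").set_index("barcode")["cluster"]

    # annotate clusters by ground-truth majority (the synthetic stand-in for
    # the reference-based label transfer used on real data)
    truth = labels.set_index("barcode")["cell_type"]
    cells = clusters.index.intersection(adata.obs_names)
    assigned = clusters.loc[cells]
    assigned = assigned[assigned >= 0]
    anno = {}
    for cl, members in assigned.groupby(assigned).groups.items():
        anno[cl] = truth.loc[members].mode().iloc[0]
    celltype_of = assigned.map(anno)
    sub = adata[celltype_of.index]
    types = pd.Series(celltype_of.values, index=celltype_of.index)

    # ---------------- peaks ----------------
    top_n = cfg.top_specific or sim.n_celltypes * sim.specific_peaks_per_type
    if not (resume and _done(run, "peaks")):
        hq = spc.select_high_quality_peaks(sub, types)
        prop, scales = spc.proportion_matrix(sub, types, peaks=hq)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            var_peaks = spc.select_variable_peaks(prop, n=cfg.variable_n)
        table = spc.js_specificity(prop.loc[var_peaks], scales)
        top = spc.select_specific_peaks(table, top_n=top_n)
        pd.Series(hq).to_csv(run / "hq_peaks.tsv", sep="\t", header=False, index=False)
        top.to_csv(run / "specific_peaks.tsv", sep="\t", index=False)
        table.final.to_csv(run / "specificity.tsv", sep="\t")
    specific = pd.read_csv(run / "specific_peaks.tsv", sep="\t")

    # ---------------- map_origin ----------------
    if not (resume and _done(run, "map_origin")):
        seed = stage_seed(cfg.seed, "map_origin")
        X = sp.csr_matrix(sub.X)
        ref = pd.DataFrame(
            {n: np.asarray(X[(types == n).values].sum(axis=0)).ravel() for n in sorted(types.unique())},
            index=sub.var_names,
        )
        shared = bulk.index.intersection(ref.index)
        nbulk = origin.normalize_counts(bulk.loc[shared])
        nref = origin.normalize_counts(ref.loc[shared])
        prop, scales = spc.proportion_matrix(sub, types)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hv = pd.Index(spc.select_variable_peaks(prop, n=cfg.variable_n)).intersection(shared)
        corr, split = origin.correlate_samples_celltypes(nbulk.loc[hv], nref.loc[hv])
        corr.to_csv(run / "correlation.tsv", sep="\t")

        # name ATAC subgroups by the modal best-correlated cell type
        split_names = {}
        order = sorted(split.unique())
        argmax = corr.idxmax(axis=1)
        modal = {c: argmax[split == c].mode().iloc[0] for c in order}
        a1_type = sim.celltype_names[sim.tumor_origins[0]]
        for c in order:
            split_names[c] = "a1" if modal[c] == a1_type else "a2"
        subgroups = split.map(split_names).rename("subgroup")
        subgroups.rename_axis("sample").to_csv(run / "subgroups_atac.tsv", sep="\t")
        _write_json({split_names[c]: modal[c] for c in order}, run / "pairing.json")

        panel, plabels, _ = origin.build_pseudobulk_panel(
            sub, types, cells_per_rep=cfg.panel_cells, reps=cfg.panel_reps, seed=seed)
        feat_peaks = pd.Index(specific["peak_id"]).intersection(nbulk.index)
        models = origin.train_similarity_models(
            panel, plabels, feat_peaks, n_folds=cfg.cv_folds, seed=seed)
        scores = origin.predict_similarity(models, nbulk)
        scores.to_csv(run / "similarity.tsv", sep="\t")

        # overlap test: tumor subgroup top peaks vs per-type specific peaks
        peak_coords = adata.var.copy()
        peak_coords["peak_id"] = adata.var_names
        peak_coords = peak_coords.reset_index(drop=True)
        type_sets = {
            t: peak_coords[peak_coords["peak_id"].isin(g["peak_id"])][["chrom", "start", "end"]]
            for t, g in specific.groupby("cell_type")
        }
        pooled = peak_coords[peak_coords["peak_id"].isin(specific["peak_id"])][["chrom", "start", "end"]]
        bulk_peak_tab = io.read_bed(run / "bulk_peaks.bed").rename(columns={"name": "peak_id", "score": "label"})
        cancer_sets = {}
        for name, grp in subgroups.groupby(subgroups):
            top_peaks = origin.top_ranked_peaks(nbulk[grp.index], n=top_n)
            cancer_sets[name] = bulk_peak_tab[bulk_peak_tab["peak_id"].isin(top_peaks)][["chrom", "start", "end"]]
        overlap = origin.permutation_overlap_test(
            cancer_sets, type_sets, pooled, n_perm=cfg.n_perm, seed=seed)
        overlap.to_csv(run / "overlap_test.tsv", sep="\t", index=False)

        diff = origin.differential_peaks(
            bulk.loc[shared], subgroups, lfc_threshold=cfg.diff_lfc,
            fdr_threshold=cfg.diff_fdr, logcpm_threshold=cfg.diff_logcpm)
        diff.to_csv(run / "differential_peaks.tsv", sep="\t")
    subgroups = pd.read_csv(run / "subgroups_atac.tsv", sep="\t", index_col=0)["subgroup"]
    pairing = json.load(open(run / "pairing.json"))

    # ---------------- network ----------------
    if not (resume and _done(run, "network")):
        seed = stage_seed(cfg.seed, "network")
        ptab = sub.var.copy()
        ptab["peak_id"] = sub.var_names
        comb, nodes = coaccess.genebody_accessibility(sub.X, ptab.reset_index(drop=True), genome.genes)
        from sklearn.decomposition import TruncatedSVD
        emb = TruncatedSVD(
            min(20, min(sub.shape) - 1), random_state=seed
        ).fit_transform(sp.csr_matrix(sub.X, dtype=float))
        agg = coaccess.aggregate_cells(comb, emb, k=cfg.agg_k, n_aggregates=cfg.n_aggregates, seed=seed)
        edges = coaccess.coaccessibility(
            agg, nodes, window=cfg.coaccess_window, step=cfg.coaccess_step,
            constraint=cfg.coaccess_constraint, score_cutoff=cfg.edge_cutoff)
        act = coaccess.gene_activity(edges, comb, nodes, score_cutoff=cfg.edge_cutoff)
        act.index = sub.obs_names
        edges.to_csv(run / "edges.tsv", sep="\t", index=False)
        act.to_csv(run / "gene_activity.tsv", sep="\t")
    activity = pd.read_csv(run / "gene_activity.tsv", sep="\t", index_col=0)

    # ---------------- features ----------------
    if not (resume and _done(run, "features")):
        act_types = types.reindex(activity.index)
        ct_sets, _ = ft.celltype_feature_genes(activity, act_types)
        gene_counts = _bulk_gene_counts(bulk, adata.var, genome.genes)
        sg_sets, _ = ft.subgroup_feature_genes(
            gene_counts, subgroups, lfc_threshold=cfg.gene_lfc,
            fdr_threshold=cfg.diff_fdr, logcpm_threshold=cfg.gene_logcpm)
        derived = ft.derive_origin_features(ct_sets, sg_sets, pairing)
        _write_json({k: sorted(v) for k, v in ct_sets.items()}, run / "celltype_features.json")
        _write_json({k: sorted(v) for k, v in sg_sets.items()}, run / "subgroup_features.json")
        _write_json({k: sorted(v) for k, v in derived.sets.items()}, run / "origin_features.json")
    derived = ft.OriginDerivedFeatures(
        {k: set(v) for k, v in json.load(open(run / "origin_features.json")).items()})

    # ---------------- subtype ----------------
    if not (resume and _done(run, "subtype")):
        sample_labels = ft.subgroup_bulk_samples(expr, derived, a2_name="a2")
        sample_labels.rename_axis("sample").to_csv(run / "sample_subgroups.tsv", sep="\t")
    sample_labels = pd.read_csv(run / "sample_subgroups.tsv", sep="\t", index_col=0)["subgroup"]

    # ---------------- enrichment ----------------
    if not (resume and _done(run, "enrichment")):
        a2_like = sample_labels.index[sample_labels == "a2_Like"]
        observed = int(meta.loc[a2_like, "cimp"].sum())
        result = ft.cimp_bootstrap_test(
            n_total=len(sample_labels), n_subgroup=len(a2_like),
            n_labeled=int(meta["cimp"].sum()), observed=observed,
            reps=cfg.bootstrap_reps, seed=stage_seed(cfg.seed, "enrichment"))
        _write_json(result.to_dict(), run / "enrichment.json")
    enrichment = json.load(open(run / "enrichment.json"))

    # ---------------- manifest ----------------
    checksums = {}
    for stage, files in STAGE_OUTPUTS.items():
        for f in files:
            p = run / f
            if p.exists():
                checksums[f] = _sha256(p)
    manifest = {
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in STAGE_OUTPUTS},
        "checksums": checksums,
        "enrichment": enrichment,
    }
    _write_json(manifest, run / "manifest.json")
    return manifest


def _bulk_gene_counts(bulk: pd.DataFrame, peak_table: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Gene-level bulk counts: sum of peak counts inside each genebody."""
    pt = peak_table.copy()
    pt["peak_id"] = peak_table.index
    pt = pt.reset_index(drop=True)
    rows = {}
    for _, g in genes.iterrows():
        inside = (
            (pt["chrom"] == g.chrom) & (pt["start"] < g.end) & (pt["end"] > g.start)
        )
        ids = [p for p in pt.loc[inside, "peak_id"] if p in bulk.index]
        rows[g.gene_id] = bulk.loc[ids].sum(axis=0) if ids else pd.Series(0, index=bulk.columns)
    return pd.DataFrame(rows).T
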