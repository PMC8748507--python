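"""Synthetic kidney scATAC / bulk tumor cohort generators.

Every generator is a pure function of (genome, config): the config seed is
split into fixed substreams, so identical configs give bit-identical
outputs regardless of call order.  The generated structure mirrors what the
downstream pipeline assumes:

* per-barcode fragment streams whose insert sizes show ~200 bp nucleosomal
  periodicity for genuine cells and an aperiodic background otherwise;
* a peak-by-cell count matrix in which each cell type carries a disjoint
  set of specific peaks (high accessibility in its own type, low elsewhere)
  on top of shared housekeeping peaks;
* bulk tumor peak profiles that are multinomial mixtures dominated by one
  originating cell type, plus tumor-private peaks absent from all normal
  types;
* a bulk expression cohort whose host subgroup carries elevated marker-gene
  expression and all of the clinical (CIMP-like) labels.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SimulationConfig
from .genome import ToyGenome

PEAK_COLUMNS = ["chrom", "start", "end", "peak_id", "label"]


# ---------------------------------------------------------------------------
# peak landscape
# ---------------------------------------------------------------------------

def peak_layout(genome: ToyGenome, config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Deterministic disjoint peak placement plus marker-gene assignment.

    Peaks sit on a lattice (one per ``peak_width + 100`` bp slot) so they can
    never overlap.  Each cell type owns ``markers_per_type`` marker genes;
    most of its specific peaks are placed inside those genebodies, the rest
    intergenic.  Remaining slots host shared housekeeping peaks, neutral
    (low-everywhere) peaks, and tumor-private peaks.
    """
    rng = config.substream(11)
    width, step = config.peak_width, config.peak_width + 100
    # all candidate slots genome-wide
    slots = []  # (chrom, start)
    for chrom, size in genome.chrom_sizes.items():
        n_slots = (size - 100) // step
        for s in range(n_slots):
            slots.append((chrom, 50 + s * step))
    slot_df = pd.DataFrame(slots, columns=["chrom", "start"])
    slot_df["end"] = slot_df["start"] + width

    genes = genome.genes.reset_index(drop=True)
    K = config.n_celltypes
    order = rng.permutation(len(genes))
    markers: dict[str, list[str]] = {}
    marker_gene_rows: dict[str, list[int]] = {}
    idx = 0
    for t, name in enumerate(config.celltype_names):
        rows = list(order[idx : idx + config.markers_per_type])
        idx += config.markers_per_type
        markers[name] = sorted(genes.loc[rows, "gene_id"].tolist())
        marker_gene_rows[name] = rows

    free = np.ones(len(slot_df), dtype=bool)
    labels = np.full(len(slot_df), "", dtype=object)

    def slots_in(chrom: str, lo: int, hi: int) -> np.ndarray:
        m = (slot_df["chrom"].values == chrom) & (slot_df["start"].values >= lo) & (slot_df["end"].values <= hi)
        return np.flatnonzero(m & free)

    # slots inside any genebody: type-specific peaks must not fall into a
    # non-marker gene, or that gene would silently become a planted marker
    in_any_gene = np.zeros(len(slot_df), dtype=bool)
    for _, g in genes.iterrows():
        in_any_gene |= (
            (slot_df["chrom"].values == g.chrom)
            & (slot_df["start"].values >= g.start)
            & (slot_df["end"].values <= g.end)
        )

    # type-specific peaks: genebody portion round-robin over marker genes
    for t, name in enumerate(config.celltype_names):
        n_gb = int(round(config.genebody_specific_fraction * config.specific_peaks_per_type))
        n_ig = config.specific_peaks_per_type - n_gb
        placed = 0
        gi = 0
        gene_rows = marker_gene_rows[name]
        per_gene_pool = [slots_in(genes.loc[r, "chrom"], genes.loc[r, "start"], genes.loc[r, "end"]) for r in gene_rows]
        per_gene_pool = [list(rng.permutation(p)) for p in per_gene_pool]
        while placed < n_gb:
            pool = per_gene_pool[gi % len(per_gene_pool)]
            gi += 1
            while pool:
                s = pool.pop()
                if free[s]:
                    free[s] = False
                    labels[s] = name
                    placed += 1
                    break
            if all(len(p) == 0 for p in per_gene_pool):
                break
        n_ig += n_gb - placed  # make up any shortfall intergenically
        pick = rng.choice(np.flatnonzero(free & ~in_any_gene), size=n_ig, replace=False)
        free[pick] = False
        labels[pick] = name

    for count, lab in ((config.n_housekeeping, "housekeeping"), (config.n_private_peaks, "tumor_private")):
        pick = rng.choice(np.flatnonzero(free), size=count, replace=False)
        free[pick] = False
        labels[pick] = lab

    n_neutral = config.n_peaks - K * config.specific_peaks_per_type - config.n_housekeeping
    if n_neutral < 0:
        raise ValueError("n_peaks too small for the requested specific/housekeeping peaks")
    pick = rng.choice(np.flatnonzero(free), size=n_neutral, replace=False)
    labels[pick] = "neutral"

    keep = labels != ""
    peaks = slot_df.loc[keep].copy()
    peaks["label"] = labels[keep]
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    peaks["peak_id"] = [f"peak{i:05d}" for i in range(len(peaks))]
    return peaks[PEAK_COLUMNS], markers


def cell_barcodes(config: SimulationConfig) -> pd.DataFrame:
    """Barcode table shared by the fragment and peak-matrix generators."""
    rows = []
    i = 0
    for t, n in enumerate(config.cells_per_type):
        for _ in range(n):
            rows.append({"barcode": f"CELL{i:05d}", "is_cell": True, "cell_type": config.celltype_names[t]})
            i += 1
    for j in range(config.n_background):
        rows.append({"barcode": f"BG{j:05d}", "is_cell": False, "cell_type": "background"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def _insert_sizes(rng: np.random.Generator, n: int, periodic_fraction: float, period: int, max_insert: int) -> np.ndarray:
    """Mixture insert-size model: sub-nucleosomal exponential plus Gaussians
    at 1x and 2x the nucleosome period."""
    u = rng.random(n)
    sizes = np.empty(n)
    sub = u >= periodic_fraction
    sizes[sub] = rng.exponential(60.0, sub.sum()) + 25.0
    per = ~sub
    n_per = per.sum()
    if n_per:
        two = rng.random(n_per) < 0.25
        s = np.where(
            two,
            rng.normal(2 * period, period * 0.125, n_per),
            rng.normal(period, period * 0.1, n_per),
        )
        sizes[per] = s
    return np.clip(np.round(sizes), 10, max_insert).astype(np.int64)


def simulate_fragments(
    genome: ToyGenome, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the deduplicated fragment stream and ground-truth labels.

    Returns ``(fragments, labels)``: fragments has columns (chrom, start,
    end, barcode) sorted by position; labels has (barcode, is_cell,
    cell_type).
    """
    if len(genome.chrom_sizes) == 0:  # pragma: no cover - guarded in ToyGenome
        raise ValueError("empty genome")
    rng = config.substream(12)
    peaks, _ = peak_layout(genome, config)
    barcodes = cell_barcodes(config)

    chrom_names = list(genome.chrom_sizes)
    chrom_sizes = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    chrom_w = chrom_sizes / chrom_sizes.sum()
    chrom_of_peak = pd.Categorical(peaks["chrom"], categories=chrom_names).codes.astype(np.int64)
    genes = genome.genes
    tss = genes["tss"].values.astype(np.int64)
    chrom_of_gene = pd.Categorical(genes["chrom"], categories=chrom_names).codes.astype(np.int64)

    frames = []
    for is_cell, group in ((True, barcodes[barcodes.is_cell]), (False, barcodes[~barcodes.is_cell])):
        if not len(group):
            continue
        if is_cell:
            meanlog, sdlog = config.depth_meanlog, config.depth_sdlog
            pf, tssf, peakf = config.periodic_fraction, config.tss_fraction, config.peak_fraction
        else:
            meanlog, sdlog = config.bg_depth_meanlog, config.bg_depth_sdlog
            pf, tssf, peakf = config.bg_periodic_fraction, config.bg_tss_fraction, 0.0

        depths = np.maximum(20, np.round(rng.lognormal(meanlog, sdlog, len(group)))).astype(np.int64)
        total = int(depths.sum())
        bc = np.repeat(group["barcode"].values, depths)
        if is_cell:
            types = np.repeat(pd.Categorical(group["cell_type"], categories=config.celltype_names).codes, depths)
        inserts = _insert_sizes(rng, total, pf, config.nucleosome_period, config.max_insert)

        u = rng.random(total)
        cat = np.where(u < tssf, 0, np.where(u < tssf + peakf, 1, 2))
        start = np.empty(total, dtype=np.int64)
        chrom_idx = np.empty(total, dtype=np.int64)

        m = cat == 0  # near a random TSS
        n_m = int(m.sum())
        gi = rng.integers(0, len(genes), n_m)
        center = tss[gi] + rng.integers(-900, 901, n_m)
        start[m] = center - inserts[m] // 2
        chrom_idx[m] = chrom_of_gene[gi]

        m = cat == 1  # inside a peak accessible to this cell's type
        n_m = int(m.sum())
        if n_m:
            lab = peaks["label"].values
            pick = np.empty(n_m, dtype=np.int64)
            tcodes = types[m]
            for t, name in enumerate(config.celltype_names):
                # peaks drawn proportionally to their accessibility in this type
                accs = np.flatnonzero((lab == name) | (lab == "housekeeping"))
                w = np.where(lab[accs] == name, config.p_specific, config.p_housekeeping)
                tm = tcodes == t
                pick[tm] = rng.choice(accs, size=int(tm.sum()), p=w / w.sum())
            mid = rng.integers(peaks["start"].values[pick], peaks["end"].values[pick])
            start[m] = mid - inserts[m] // 2
            chrom_idx[m] = chrom_of_peak[pick]

        m = cat == 2  # uniform background
        n_m = int(m.sum())
        ci = rng.choice(len(chrom_names), size=n_m, p=chrom_w)
        start[m] = (rng.random(n_m) * (chrom_sizes[ci] - inserts[m])).astype(np.int64)
        chrom_idx[m] = ci

        start = np.clip(start, 0, chrom_sizes[chrom_idx] - inserts - 1)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": pd.Categorical.from_codes(chrom_idx, categories=chrom_names),
                    "start": start,
                    "end": start + inserts,
                    "barcode": bc,
                }
            )
        )

    frags = pd.concat(frames, ignore_index=True)
    frags = frags.drop_duplicates(["chrom", "start", "end", "barcode"])
    frags = frags.sort_values(["chrom", "start", "end", "barcode"], kind="mergesort").reset_index(drop=True)
    frags["chrom"] = frags["chrom"].astype(str)
    return frags, barcodes


# ---------------------------------------------------------------------------
# peak-by-cell matrix
# ---------------------------------------------------------------------------

def simulate_peak_matrix(genome: ToyGenome, config: SimulationConfig) -> ad.AnnData:
    """Peak-by-cell counts for the genuine cells (AnnData, cells x peaks).

    A type-specific peak is accessible with probability ``p_specific`` in its
    own type and ``p_offtarget`` elsewhere; housekeeping peaks are accessible
    in every type.  Tumor-private peaks are excluded (absent from normals).
    """
    rng = config.substream(13)
    peaks, _ = peak_layout(genome, config)
    peaks = peaks[peaks["label"] != "tumor_private"].reset_index(drop=True)
    barcodes = cell_barcodes(config)
    cells = barcodes[barcodes.is_cell].reset_index(drop=True)

    lab = peaks["label"].values
    P = len(peaks)
    prob_by_type = {}
    for name in config.celltype_names:
        p = np.full(P, config.p_offtarget)
        p[lab == "housekeeping"] = config.p_housekeeping
        p[lab == name] = config.p_specific
        prob_by_type[name] = p

    blocks = []
    for name in config.celltype_names:
        n = int((cells["cell_type"] == name).sum())
        acc = rng.random((n, P)) < prob_by_type[name][None, :]
        counts = acc * (1 + rng.poisson(0.25, size=(n, P)))
        blocks.append(sp.csr_matrix(counts))
    X = sp.vstack(blocks).tocsr()

    adata = ad.AnnData(
        X=X,
        obs=cells.set_index("barcode")[["cell_type"]],
        var=peaks.set_index("peak_id"),
    )
    return adata


# ---------------------------------------------------------------------------
# bulk tumors
# ---------------------------------------------------------------------------

def simulate_bulk_tumors(
    adata: ad.AnnData, genome: ToyGenome, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Bulk tumor peak-count profiles as noisy origin-dominated mixtures.

    Each tumor's multinomial probabilities are ``purity * origin profile +
    (1 - purity) * mean(other type profiles)`` over the normal peaks, with
    ``private_read_fraction`` of reads diverted to tumor-private peaks.
    Per-type profiles come from the generative accessibility probabilities
    (not the finite-cell empirical means, whose sampling noise would
    otherwise be frozen into every tumor of an origin as spurious signal).

    Returns (counts peaks x samples, origin labels, peak table incl. private).
    """
    if config.purity <= 0.5:
        raise ValueError("purity <= 0.5: origin unidentifiable")
    rng = config.substream(14)
    all_peaks, _ = peak_layout(genome, config)
    private = all_peaks[all_peaks["label"] == "tumor_private"]
    normal_ids = [p for p in all_peaks["peak_id"] if p in set(adata.var_names)]

    lab = adata.var.loc[normal_ids, "label"].values
    profiles = {}
    for name in config.celltype_names:
        p = np.full(len(normal_ids), config.p_offtarget)
        p[lab == "housekeeping"] = config.p_housekeeping
        p[lab == name] = config.p_specific
        profiles[name] = p / p.sum()

    names = config.celltype_names
    cols, origins = {}, {}
    pf = config.private_read_fraction if len(private) else 0.0
    for origin_idx, n_tum in zip(config.tumor_origins, config.tumors_per_origin):
        origin = names[origin_idx]
        others = [profiles[n] for n in names if n != origin]
        base = config.purity * profiles[origin] + (1 - config.purity) * np.mean(others, axis=0)
        for i in range(n_tum):
            p = np.concatenate([base * (1 - pf), np.full(len(private), pf / max(1, len(private)))])
            p = p / p.sum()
            sample = f"TUM_{origin}_{i:02d}"
            cols[sample] = rng.multinomial(config.tumor_depth, p)
            origins[sample] = origin

    index = list(normal_ids) + private["peak_id"].tolist()
    counts = pd.DataFrame(cols, index=pd.Index(index, name="peak_id"))
    peak_table = all_peaks.set_index("peak_id").loc[index].reset_index()
    return counts, pd.Series(origins, name="origin"), peak_table


# ---------------------------------------------------------------------------
# bulk expression cohort
# ---------------------------------------------------------------------------

def simulate_expression(
    genome: ToyGenome, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-by-sample expression with a host subgroup carrying all CIMP labels.

    Samples in the a2-analogue subgroup (``subgroup_size`` of ``n_samples``)
    have the a2 origin's marker genes elevated by ``expr_log2fc``; the
    remaining samples have the a1 origin's markers elevated.  Log-normal
    multiplicative noise throughout.  All ``n_cimp`` labels are placed
    inside the host subgroup.
    """
    rng = config.substream(15)
    _, markers = peak_layout(genome, config)
    names = config.celltype_names
    a1_genes = markers[names[config.tumor_origins[0]]]
    a2_genes = markers[names[config.tumor_origins[1]]]

    genes = genome.genes["gene_id"].tolist()
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    baseline = rng.lognormal(config.expr_baseline_meanlog, config.expr_baseline_sdlog, len(genes))
    mat = baseline[:, None] * rng.lognormal(0.0, config.expr_sdlog, (len(genes), len(samples)))

    a2_samples = rng.choice(config.n_samples, size=config.subgroup_size, replace=False)
    is_a2 = np.zeros(config.n_samples, dtype=bool)
    is_a2[a2_samples] = True
    gidx = {g: i for i, g in enumerate(genes)}
    fc = 2.0 ** config.expr_log2fc
    a1_rows = [gidx[g] for g in a1_genes if g in gidx]
    a2_rows = [gidx[g] for g in a2_genes if g in gidx]
    mat[np.ix_(a2_rows, np.flatnonzero(is_a2))] *= fc
    mat[np.ix_(a1_rows, np.flatnonzero(~is_a2))] *= fc

    cimp = rng.choice(np.flatnonzero(is_a2), size=config.n_cimp, replace=False)
    is_cimp = np.zeros(config.n_samples, dtype=bool)
    is_cimp[cimp] = True

    expr = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    meta = pd.DataFrame(
        {"sample": samples, "subgroup": np.where(is_a2, "a2", "a1"), "cimp": is_cimp}
    ).set_index("sample")
    return expr, meta
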