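# origin-atlas

Tracing the cell of origin of kidney tumors from chromatin accessibility.

Papillary renal cell carcinoma (pRCC) splits into two molecular subgroups
that this kind of analysis attributes to two different normal kidney cell
types of origin — proximal tubule (PT) cells and collecting-duct principal
(CD_PC) cells — and the rarer subgroup concentrates the lethal CIMP
(CpG island methylator phenotype) variant. `origin-atlas` implements the
full computational chain that supports such a claim, as a reusable,
deterministic Python library with a synthetic data module standing in for
the (very large) raw sequencing inputs:

1. **scATAC-seq barcode QC** — per-barcode total fragments, TSS ratio
   (fraction of fragments within ±1000 bp of a transcription start site),
   and a **nucleosome banding score**: the summed smoothed spectral density
   of the insert-size histogram in the 100–300 bp period band (detrend,
   split-cosine-bell taper 0.5, 30% zero-padding, modified Daniell span 20).
   Cutoffs are the stricter of a 2-component Gaussian-mixture fit and the
   fixed floors `log10(fragments) > 3.4`, `TSS ratio > 0.15`,
   `log10(banding) > −1.75`.
2. **LSA clustering** — binary 5 kb window-by-cell matrix, log TF-IDF
   weighting `ln(1 + 10⁴·tf·idf)`, truncated SVD (components 2–40), KNN
   graph (k = 15, shared-neighbor Jaccard weights), modularity clustering
   at resolution 1, clusters with > 50 cells retained.
3. **Jensen–Shannon peak specificity** — peak-by-type accessible-cell
   proportions scaled by each type's median fragment count; for each peak
   `s(p,t) = 1 − √JSD₂(q_p, e_t)` against the one-hot distribution of type
   t, ranked by `s²` times the scaled proportion.
4. **Origin mapping** of bulk tumor ATAC profiles by three independent
   statistics: peak-overlap permutation tests (binomial tail at the
   permutation-expected overlap, BH-adjusted), Pearson correlation of
   log-CPM + quantile-normalized accessibility over shared variable peaks,
   and **similarity scores** from one-vs-rest L1-regularized binomial
   models trained on a 50-cell × 20-replicate pseudo-bulk panel with a
   per-class offset `log(f/(1−f))` and applied with offset 0.
5. **Co-accessibility networks** — genebody-anchored accessibility
   (anchor `[TSS−200, TSS+100)`), KNN cell aggregation (k = 30), and a
   graphical lasso with a distance-proportional penalty inside 500 kb
   windows (250 kb constraint, edge cutoff 0.1), from which per-gene
   activities are computed.
6. **Origin-derived features and enrichment** — cell-type feature genes
   (`pct.1 > 0.5`, `avg_logFC > 0.5`) intersected with tumor-subgroup
   feature genes from a negative-binomial exact test (`|logFC| > 1`,
   `FDR < 0.05`, `logCPM > 5`); the expression cohort is 2-cut clustered
   on these features, and the CIMP count in the resulting subgroup is
   tested by bootstrap (normal tail over 10,000 draws of n-of-N) next to
   the exact hypergeometric tail.

## Worked example

The headline statistic: a 255-sample tumor cohort holds 8 CIMP samples and
a 41-sample expression subgroup captures all 8 of them. How surprising?

```bash
origin-atlas test-enrichment -N 255 -n 41 -m 8 --observed 8 --reps 10000 --seed 0
```

```json
{
 "N": 255, "n": 41, "m": 8, "observed": 8, "reps": 10000,
 "bootstrap_mean": 1.3033,
 "bootstrap_sd": 1.0295703528711144,
 "p_normal_tail": 3.9011468298713476e-11,
 "p_hypergeometric": 2.407595488420405e-07,
 "degenerate": false
}
```

A random 41-sample subgroup recovers on average 1.3 of the 8 labels
(`41·8/255 ≈ 1.29`); observing all 8 sits more than six bootstrap SDs
above that, an upper-tail probability of ~4e-11 under the normal fit. The
exact hypergeometric tail — `P(X ≥ 8) = Π(41−i)/(255−i) ≈ 2.4e-7` — is
reported alongside because a normal fit understates a far tail; both say
the subgroup captures the label far beyond chance.

The full synthetic pipeline (fragments → QC → clustering → specific peaks
→ origin mapping → networks → features → subtyping → enrichment) runs in
well under a minute at the reduced cohort size:

```bash
origin-atlas run --outdir run1 --seed 0 --small
```

which finishes with `run complete: run1/manifest.json`; the manifest's
`enrichment` block for that seed reads `observed: 8`, `n: 41`,
`p_normal_tail: 2.79e-11`, `p_hypergeometric: 2.41e-7` — the planted
8-of-41 geometry recovered end to end from simulated fragments. Inspect
intermediate results with `origin-atlas map-origin --run-dir run1 --method
similarity`, `origin-atlas features --run-dir run1`, and `origin-atlas
subtype --run-dir run1`.

## Layout

```
src/origin_atlas/
  genome.py      toy genome (chromosomes + gene table, BED conventions)
  config.py      simulation parameters (the study conditions)
  simulate.py    fragment / peak-matrix / bulk-tumor / expression generators
  qc.py          barcode QC: TSS ratio, banding periodogram, mixture cutoffs
  lsa.py         window matrix, log TF-IDF, SVD, KNN + modularity clustering
  specificity.py interval merging, HQ/variable peaks, JS specificity
  origin.py      overlap tests, normalization, similarity models, NB test
  coaccess.py    genebody anchors, aggregation, graphical lasso, activity
  features.py    feature genes, bulk subgrouping, enrichment testing
  pipeline.py    staged orchestration with manifest + resume
  cli.py         `origin-atlas` command group
```

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
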