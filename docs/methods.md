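# Methods

This note documents the models, the synthetic cohort, the numerical
choices, and what the test suite does and does not demonstrate.

## The synthetic cohort

All inputs are generated by `origin_atlas.simulate` as pure functions of a
`SimulationConfig`; a fixed seed makes every artifact bit-reproducible.
The generators emulate the statistical structure the analysis assumes, not
raw sequencing:

* **Toy genome.** Two chromosomes of 25 Mb with 200 non-overlapping genes
  (10–30 kb) on a jittered lattice. The genome is deliberately larger than
  a "smallest possible" toy: at realistic post-QC depths (median ~8,000
  fragments per cell, matching the `log10 > 3.4` retention floor) a 10 Mb
  genome saturates the binarized 5 kb window matrix — every window is hit
  in every cell and all type signal vanishes. 50 Mb keeps the window
  matrix at ~29% density, where latent-semantic clustering behaves like it
  does on real data, while the whole pipeline still runs in about a
  minute. Coordinates are 0-based half-open (BED) everywhere; the TSS is
  the genebody start on `+` and the genebody end on `−`, and the gene
  anchor used by the co-accessibility stage is `[TSS−200, TSS+100)`
  mirrored on `−`.
* **Peak landscape.** 2,000 peaks of 500 bp on a 600 bp lattice (hence
  never overlapping): 150 specific peaks per cell type (disjoint by
  construction; 70% inside that type's 25 designated marker genebodies,
  the rest strictly intergenic so no undeclared gene becomes a marker),
  500 housekeeping peaks shared by all types, 50 tumor-private peaks
  absent from all normal cells, and neutral low-accessibility filler.
* **Fragments.** Per-cell depths are log-normal (median 8,000, σ_log 0.3
  for genuine cells; 600, σ_log 0.5 for background barcodes). Insert sizes
  follow a mixture of a sub-nucleosomal exponential (scale 60 bp + 25) and
  Gaussians at 1× and 2× the 200 bp nucleosome period (weights 3:1),
  with periodic fraction 0.5 for genuine cells and 0 for background. 25%
  of genuine-cell fragments land within ±900 bp of a random TSS, 45% in
  peaks accessible to the cell's type — drawn proportionally to the peak's
  accessibility probability, so specific peaks receive twice the
  per-peak rate of housekeeping peaks — and the rest uniformly. Fragments
  are deduplicated on (chrom, start, end, barcode).
* **Peak-by-cell counts.** Bernoulli accessibility (own-type specific
  0.6, off-type 0.05, housekeeping 0.3) times `1 + Poisson(0.25)`.
* **Bulk tumors.** Each tumor draws `tumor_depth = 200,000` reads from a
  multinomial with probabilities `purity·(origin profile) + (1−purity)·
  mean(other profiles)`, plus 5% of reads on tumor-private peaks. Origin
  profiles are the *generative* accessibility probabilities, not empirical
  means over the simulated cells: empirical profiles freeze finite-cell
  sampling noise into every tumor of an origin, which surfaces as spurious
  but perfectly reproducible "subgroup-specific" signal at low-signal
  peaks. Default cohort: 30 tumors of one origin, 4 of the other
  (mirroring the lopsided split such cohorts show), purity 0.8.
* **Expression cohort.** 255 samples, 41 in the minority (a2) subgroup;
  the paired origin's marker genes are elevated 4-fold (log2FC 2) in their
  subgroup over a log-normal baseline (σ_log 0.4); all 8 CIMP labels are
  placed inside the a2 subgroup. With the effect set to zero the cohort
  has no 2-cluster structure (silhouette < 0.25), which the suite checks.

## Barcode QC

The banding score operates on the insert-size histogram (counts per bp,
sizes 1–1000 — the maximum size is a config choice, as the procedure it
follows does not state one), not the raw size sequence: the statistic is
order-free and the histogram is its permutation-invariant sufficient
series. Pipeline: remove the linear trend, taper a total proportion 0.5
with a split cosine bell, zero-pad by 30%, periodogram, one pass of a
modified Daniell kernel of span 20 (half-weight endpoints, circular), sum
densities at frequencies in `[1/300, 1/100]` cycles/bp.

One consequence worth recording: the span-20 kernel is ~0.016 cycles/bp
wide, more than twice the whole 100–300 bp band, so even a pure 200 bp
cosine keeps only ~45% of its smoothed mass inside the band. The band
still dominates overwhelmingly (its width share is 1.4%), and the genuine
vs background separation is what matters operationally (AUROC ≈ 1 in the
suite); the tests assert dominance and oracle agreement rather than a
near-total mass fraction, which the stated smoothing cannot produce.

Cutoffs: a 2-component Gaussian mixture (5 EM restarts, fixed seed) per
statistic; candidate threshold at the posterior-equality point between the
means (closed-form quadratic); the returned threshold is
`max(candidate, default)` with defaults 3.4 / 0.15 / −1.75. A fit is
declared degenerate — and the default used — when a component weight is
below 0.02, the means are within 0.25 pooled SD, or the 2-component model
loses to a single Gaussian on BIC (the mixture tool's own model-selection
rule; without it a plain unimodal Gaussian is happily split in two).
Retention requires strictly exceeding all three thresholds.

## Clustering

Binary window matrix (both fragment ends are Tn5 insertion sites; last
partial window kept), zero-coverage windows dropped, then the top
`ceil(5%)` by cell coverage removed under a deterministic ordering
(coverage descending, window index ascending — a stable rank that removes
exactly the quota even under total ties). TF-IDF: `ln(1 + 10⁴·tf·idf)`
with `tf = x / cell total`, `idf = n_cells / window count`. Truncated SVD
to 40 components; component 1 is excluded from the KNN graph (it tracks
depth — the suite verifies it carries the maximum depth correlation).
Edges are weighted by shared-neighbor Jaccard similarity (the KNN weighting
is not pinned down by the procedure this follows; Jaccard is the common
choice in scATAC practice). Modularity optimization uses the Leiden
algorithm (`leidenalg`, RBConfiguration partition, resolution 1, fixed
seed) — an explicitly sanctioned stand-in for Louvain behind the same
interface, chosen because it exposes a seed and reproduces bit-identically.
Clusters of ≤ 50 cells are marked unassigned. Inputs are canonicalized by
barcode order, which is what makes the stage invariant to input order.

## Peak specificity

High-quality peaks: accessible in strictly more than 5% of the cells of
at least one cluster. Variable peaks: vst-style standardized variance of
the peak-by-type proportion rows against a lowess trend of log10 variance
on log10 mean (span 0.3), z-values clipped at √(number of types). With a
desk-scale peak count the default request of 50,000 keeps every peak
(matching the source setting, where the request exceeds nothing); the
clip makes the statistic coarse at K = 3 columns, so the final
specificity ranking — not variable selection — is what the synthetic
validation leans on. Specificity: scale each type's proportions by the
type's median per-cell fragment count, normalize each peak row to a
distribution q, and score `s = 1 − √JSD₂(q, e_t)` (base-2 logs bound JSD
to [0, 1]); final score `s²` × scaled proportion; top (peak, type) pairs
deduplicated by peak, exact ties to the lexicographically first type. The
pipeline's default cut is K × (specific peaks per type) pairs — the
cohort-scaled analogue of a 20,000-of-550,000 cut.

## Origin mapping

* **Overlap**: fraction of tumor peaks intersecting a type's specific
  peaks; the null draws the same number of peaks from the pooled specific
  set 1,000 times; p is the one-sided binomial upper tail at the
  permutation-expected fraction (enrichment is the hypothesis of
  interest), BH-adjusted across pairs.
* **Correlation**: `log2 CPM` with a library-scaled prior count of 5,
  quantile normalization (ties receive the mean of their quantile values),
  Pearson correlation over the shared variable peaks, averaged within
  cell-type groups; hierarchical clustering of the correlation rows
  (correlation distance, average linkage, cut at 2) splits the cohort.
* **Similarity**: pseudo-bulk panel of 20 replicates × 50-cell sums per
  type (sampling with replacement, with a warning, only when a type is
  smaller than one replicate), normalized as above; one L1-regularized
  binomial model per type with the per-observation offset `log(f/(1−f))`
  and no free intercept, features standardized; λ chosen by 10-fold
  stratified CV as the largest value within one standard error of the
  deviance minimum ("the largest admissible penalty"); prediction at
  offset 0, so an all-zero coefficient vector scores 0.5 everywhere. The
  solver is an in-package coordinate-descent IRLS lasso (numba-compiled,
  warm-started along the λ path); a unit test pins it against statsmodels'
  penalized GLM at a fixed λ.
* **Differential features**: an explicit negative-binomial exact test.
  Counts are scaled to a common effective library size estimated by
  median-of-ratios (robust to composition: with abundant one-sided
  changes, raw column totals drag every null feature's normalized value
  and wreck the FDR); a single common dispersion is estimated by pooled
  method of moments `Σ(s² − μ)/Σμ²`; per feature, the two group sums are
  compared conditionally on their total (NB sums with sizes n_g/φ;
  binomial in the Poisson limit φ→0), with the two-sided p summing all
  outcomes no likelier than the observed one. Thresholds are applied as
  strict inequalities: |log2FC| (computed with a 0.5 pseudocount on
  normalized group means) above the cut, BH-FDR below, average log2-CPM
  above. The suite verifies null calibration (type-I at α = 0.05 inside
  the binomial CI over 2,000 features) and recovery of planted 8-fold
  effects (recall ≥ 0.9 at empirical FDR ≤ 0.1).

## Co-accessibility and gene activity

Genebody accessibility appends one row per gene (sum of peaks overlapping
the genebody; zero rows kept) anchored at the −200/+100 TSS window.
Cells are aggregated over k = 30 nearest neighbors of shuffled seed cells
(without replacement across seeds; aggregates sharing > 90% of members
dropped). Within overlapping 500 kb windows (step 250 kb) node vectors
are log1p-scaled and standardized and a graphical lasso (block coordinate
descent with element-wise penalties) estimates the precision matrix with
penalty `0.25 · d/250 kb` and an effectively infinite penalty beyond the
250 kb constraint, so distal pairs can never form edges. The fixed,
config-exposed penalty scale replaces an adaptive distance-parameter
search — a deliberate determinism/simplicity trade recorded here; scores
(negated scaled precision entries, i.e. partial correlations) for pairs
seen in multiple windows are averaged and edges kept at ≥ 0.1.
Non-convergent windows are skipped with a warning. Gene activity is the
genebody signal plus all peaks linked to the gene's anchor at or above
the cutoff, normalized per cell to 10,000.

At vanishing penalty the solver reproduces the inverse covariance to
1e-6 on a well-conditioned toy (tested); at infinite penalty it returns
the diagonal.

## Features, subtyping, enrichment

Cell-type feature genes: remove genes active in fewer than 10 cells; per
type vs rest require `pct.1 > 0.5`, `avg_logFC = ln((μ_in+1)/(μ_out+1)) >
0.5`, and a BH-adjusted one-sided Wilcoxon rank-sum p < 0.05 (the rank
test is a configurable extra filter; the named thresholds alone are
permissive on desk-scale data). Subgroup feature genes reuse the NB
machinery on genebody-summed bulk counts at `|logFC| > 1, FDR < 0.05,
logCPM > 5`. Origin-derived features are the per-pair intersections;
empty intersections warn rather than fail. The expression cohort is
z-scored per gene over the pooled features and 2-cut clustered
(correlation distance, average linkage); the cluster with the higher mean
z over the a2 features is `a2_Like`.

Enrichment: draw n of N without replacement 10,000 times (the
hypergeometric sampler — which is that procedure — generates the
counts), fit a normal with the sample mean and sample SD, and report the
upper tail at the observed count; the exact hypergeometric `P(X ≥ obs)`
is always reported alongside, because a normal fit misstates far tails
(at the 255/41/8 geometry: ~3e-11 versus the exact 2.4e-7). Both numbers
are intentionally kept: the normal-tail value mirrors the bootstrap
procedure, the hypergeometric is its exact oracle. A zero bootstrap SD
flags the result as degenerate with an indicator p.

## Pipeline

Stages run in a write-once run directory with resume-on-missing-output
semantics; every stochastic stage derives its seed as
`SHA-256(global_seed:stage_name) mod 2³¹`. The manifest records config,
per-stage seeds, and SHA-256 checksums of all outputs; the suite asserts
checksum equality across independent runs. The end-to-end tests use a
reduced cohort (two types × 90 cells, 140 background barcodes, 1,200
peaks, 24 + 8 tumors) — the package's desk-scale configuration for
integration checks — while module-level validation uses the full default
cohort (three types × 200 cells, 300 background, 2,000 peaks, 100 tumors
where origin-assignment rates are measured).

## What the synthetic validation does not show

The generators produce single-batch, doublet-free, copy-number-neutral
data with homoscedastic noise and exactly disjoint type-specific peak
sets. Passing tests therefore demonstrate the correctness and calibration
of the implementations under their stated models — not robustness to
batch effects, ambient contamination, annotation error, or the milder
effect sizes of real cohorts. The similarity models are tested at class
counts (2–11 types) and feature counts (hundreds) far below the real
regime; the graphical-lasso penalty is fixed rather than adaptively
calibrated; and peak calling itself is upstream of this package (peak
intervals are inputs).
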