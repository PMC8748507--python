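"""Barcode quality control.

Each barcode is scored on three criteria: total fragment count, the
fraction of fragments within +/-1000 bp of any TSS, and a nucleosome
banding score -- the summed smoothed spectral density of the insert-size
histogram in the 100-300 bp period band.  Cutoffs are the stricter of a
2-component Gaussian-mixture fit and fixed defaults (log10 fragments > 3.4,
TSS ratio > 0.15, log10 banding > -1.75); barcodes must exceed all three
strictly to be retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from sklearn.mixture import GaussianMixture

from .genome import ToyGenome

DEFAULT_LOG10_FRAGMENTS = 3.4
DEFAULT_TSS_RATIO = 0.15
DEFAULT_LOG10_BANDING = -1.75

#: longest insert size entering the periodogram (bp)
MAX_INSERT_SIZE = 1000


@dataclass
class QCCutoffs:
    log10_fragments: float = DEFAULT_LOG10_FRAGMENTS
    tss_ratio: float = DEFAULT_TSS_RATIO
    log10_banding: float = DEFAULT_LOG10_BANDING
    provenance: dict[str, str] = field(
        default_factory=lambda: {"log10_fragments": "default", "tss_ratio": "default", "log10_banding": "default"}
    )


# ---------------------------------------------------------------------------
# TSS ratio
# ---------------------------------------------------------------------------

def _merged_tss_windows(genome: ToyGenome, flank: int = 1000) -> dict[str, np.ndarray]:
    """Merged [TSS - flank, TSS + flank) windows per chromosome."""
    out = {}
    for chrom, sub in genome.genes.groupby("chrom", sort=True):
        starts = np.maximum(0, sub["tss"].values - flank)
        ends = np.minimum(genome.chrom_sizes[chrom], sub["tss"].values + flank)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        merged_s, merged_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        out[chrom] = np.array([merged_s, merged_e])
    return out


def tss_overlap_flags(frags: pd.DataFrame, genome: ToyGenome, flank: int = 1000) -> np.ndarray:
    """Boolean per fragment: does [start, end) intersect any TSS window?"""
    windows = _merged_tss_windows(genome, flank)
    hit = np.zeros(len(frags), dtype=bool)
    for chrom, idx in frags.groupby("chrom", sort=False).indices.items():
        win = windows.get(chrom)
        if win is None:
            continue
        ws, we = win
        s = frags["start"].values[idx]
        e = frags["end"].values[idx]
        # candidate window: first whose end is beyond the fragment start
        j = np.searchsorted(we, s, side="right")
        ok = j < len(ws)
        jj = np.minimum(j, len(ws) - 1)
        hit[idx] = ok & (ws[jj] < e)
    return hit


def compute_tss_ratio(frags: pd.DataFrame, genome: ToyGenome, flank: int = 1000) -> float:
    """Fraction of one barcode's fragments intersecting a TSS window."""
    if len(frags) == 0:
        return float("nan")
    return float(tss_overlap_flags(frags, genome, flank).mean())


# ---------------------------------------------------------------------------
# banding score
# ---------------------------------------------------------------------------

def insert_size_histogram(sizes: np.ndarray, max_size: int = MAX_INSERT_SIZE) -> np.ndarray:
    """Counts per insert size 1..max_size (index 0 is size 1)."""
    sizes = np.asarray(sizes)
    sizes = sizes[(sizes >= 1) & (sizes <= max_size)]
    return np.bincount(sizes, minlength=max_size + 1)[1:]


def _split_cosine_bell(n: int, p: float) -> np.ndarray:
    """Split cosine bell tapering p of the series in total (p/2 each end)."""
    w = np.ones(n)
    m = int(np.floor(n * p / 2))
    if m > 0:
        t = np.arange(m)
        ramp = 0.5 * (1 - np.cos(np.pi * (t + 0.5) / m))
        w[:m] = ramp
        w[n - m :] = ramp[::-1]
    return w


def periodogram(series: np.ndarray, pad: float = 0.3, taper: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Detrended, tapered, zero-padded periodogram of an evenly spaced series.

    Returns (frequencies in cycles per bp, spectral densities), excluding
    frequency zero.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    t = np.arange(n)
    slope, intercept = np.polyfit(t, x, 1)
    x = x - (slope * t + intercept)
    x = x * _split_cosine_bell(n, taper)
    n_pad = int(np.ceil(n * (1 + pad)))
    x = np.concatenate([x, np.zeros(n_pad - n)])
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    freqs = np.fft.rfftfreq(n_pad)
    return freqs[1:], spec[1:]


def smooth_daniell(spec: np.ndarray, span: int = 20) -> np.ndarray:
    """One pass of a modified Daniell kernel (half-weight endpoints)."""
    m = span // 2
    w = np.full(2 * m + 1, 1.0 / (2 * m))
    w[0] = w[-1] = 1.0 / (4 * m)
    return convolve1d(spec, w, mode="wrap")


def compute_banding_score(
    hist: np.ndarray,
    low_period: float = 100.0,
    high_period: float = 300.0,
    pad: float = 0.3,
    taper: float = 0.5,
    span: int = 20,
    min_fragments: int = 100,
) -> float:
    """Summed smoothed spectral density in the nucleosomal period band.

    ``hist`` is the insert-size histogram (counts per bp, sizes 1..S).
    Returns NaN when the histogram holds fewer than ``min_fragments``
    fragments (the periodogram of a near-empty series is meaningless).
    """
    hist = np.asarray(hist, dtype=float)
    if hist.sum() < min_fragments:
        return float("nan")
    freqs, spec = periodogram(hist, pad=pad, taper=taper)
    smoothed = smooth_daniell(spec, span=span)
    band = (freqs >= 1.0 / high_period) & (freqs <= 1.0 / low_period)
    return float(smoothed[band].sum())


# ---------------------------------------------------------------------------
# QC table
# ---------------------------------------------------------------------------

def barcode_qc_table(
    frags: pd.DataFrame, genome: ToyGenome, min_fragments_for_banding: int = 100
) -> pd.DataFrame:
    """Per-barcode QC statistics: n_fragments, tss_ratio, banding_score."""
    hit = tss_overlap_flags(frags, genome)
    sizes = (frags["end"] - frags["start"]).values
    rows = []
    for bc, idx in frags.groupby("barcode", sort=True).indices.items():
        hist = insert_size_histogram(sizes[idx])
        rows.append(
            {
                "barcode": bc,
                "n_fragments": len(idx),
                "tss_ratio": float(hit[idx].mean()),
                "banding_score": compute_banding_score(hist, min_fragments=min_fragments_for_banding),
            }
        )
    return pd.DataFrame(rows).set_index("barcode")


# ---------------------------------------------------------------------------
# bimodal cutoffs
# ---------------------------------------------------------------------------

def fit_bimodal_cutoff(
    values: np.ndarray,
    default_threshold: float = -np.inf,
    seed: int = 0,
    min_weight: float = 0.02,
    min_separation: float = 0.25,
) -> tuple[float, str]:
    """Stricter of a fitted 2-Gaussian mixture boundary and a default floor.

    The candidate cutoff is the point between the two component means where
    the posterior probabilities are equal.  Degenerate fits fall back to the
    default: a component weight below ``min_weight``, means closer than
    ``min_separation`` pooled SDs, or a two-component model that does not
    beat a single Gaussian on BIC (the mixture tool's own model-selection
    rule, which is what declares a distribution unimodal).  Returns
    (threshold, provenance).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 20:
        raise ValueError("need at least 20 finite values to fit a cutoff")
    X = values.reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(X)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=seed).fit(X)
    if gm.bic(X) >= gm1.bic(X):
        return float(default_threshold), "default"

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    mu1, mu2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    pooled = np.sqrt(0.5 * (s1**2 + s2**2))
    if min(w1, w2) < min_weight or (mu2 - mu1) < min_separation * pooled:
        return float(default_threshold), "default"

    # posterior equality: w1 N(x; mu1, s1) = w2 N(x; mu2, s2) -> quadratic in x
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2) + np.log(w1 / s1) - np.log(w2 / s2)
    if abs(a) < 1e-12:
        candidate = -c / b if abs(b) > 1e-12 else 0.5 * (mu1 + mu2)
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            candidate = 0.5 * (mu1 + mu2)
        else:
            roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
            inside = roots[(roots > mu1) & (roots < mu2)]
            candidate = float(inside[0]) if len(inside) else 0.5 * (mu1 + mu2)
    if candidate >= default_threshold:
        return float(candidate), "fitted"
    return float(default_threshold), "default"


def fit_qc_cutoffs(qc: pd.DataFrame, seed: int = 0) -> QCCutoffs:
    """Fit all three bimodal cutoffs with the stated defaults as floors."""
    with np.errstate(divide="ignore"):
        lf = np.log10(qc["n_fragments"].values.astype(float))
        lb = np.log10(qc["banding_score"].values.astype(float))
    t_frag, p_frag = fit_bimodal_cutoff(lf, DEFAULT_LOG10_FRAGMENTS, seed=seed)
    t_tss, p_tss = fit_bimodal_cutoff(qc["tss_ratio"].values, DEFAULT_TSS_RATIO, seed=seed)
    t_band, p_band = fit_bimodal_cutoff(lb, DEFAULT_LOG10_BANDING, seed=seed)
    return QCCutoffs(
        t_frag, t_tss, t_band,
        {"log10_fragments": p_frag, "tss_ratio": p_tss, "log10_banding": p_band},
    )


def filter_barcodes(qc: pd.DataFrame, cutoffs: QCCutoffs) -> tuple[pd.Index, dict[str, int]]:
    """Barcodes strictly exceeding all three thresholds, plus failure counts.

    A missing (NaN) banding score fails the banding criterion.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        lf = np.log10(qc["n_fragments"].values.astype(float))
        lb = np.log10(qc["banding_score"].values.astype(float))
    pass_frag = lf > cutoffs.log10_fragments
    pass_tss = qc["tss_ratio"].values > cutoffs.tss_ratio
    pass_band = np.where(np.isnan(lb), False, lb > cutoffs.log10_banding)
    keep = pass_frag & pass_tss & pass_band
    failures = {
        "n_fragments": int((~pass_frag).sum()),
        "tss_ratio": int((~pass_tss).sum()),
        "banding_score": int((~pass_band).sum()),
    }
    return qc.index[keep], failures
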