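"""Toy genome container: chromosome sizes and a gene table.

Coordinates are 0-based half-open (BED convention) throughout the package.
The transcription start site (TSS) of a '+' strand gene is its genebody
start; for a '-' strand gene it is the genebody end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


@dataclass(frozen=True)
class ToyGenome:
    """Chromosome names/lengths plus a gene annotation table.

    ``genes`` columns: gene_id, chrom, start, end, strand ('+'/'-'), tss.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        if len(self.chrom_sizes) == 0:
            raise ValueError("empty genome")
        g = self.genes
        if len(g):
            for _, row in g.iterrows():
                size = self.chrom_sizes.get(row.chrom)
                if size is None or row.start < 0 or row.end > size or row.end <= row.start:
                    raise ValueError(f"gene {row.gene_id} outside chromosome bounds")
                expected = row.start if row.strand == "+" else row.end
                if row.tss != expected:
                    raise ValueError(f"gene {row.gene_id}: TSS inconsistent with strand")

    @property
    def total_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def chrom_offsets(self) -> dict[str, int]:
        """Cumulative start offset of each chromosome in a linearized genome."""
        off, cum = {}, 0
        for c, s in self.chrom_sizes.items():
            off[c] = cum
            cum += int(s)
        return off


def toy_genome(
    n_chroms: int = 2,
    chrom_size: int = 25_000_000,
    n_genes: int = 200,
    gene_length_range: tuple[int, int] = (10_000, 30_000),
    seed: int = 0,
) -> ToyGenome:
    """Build a deterministic toy genome.

    Genes are laid on an even lattice (one per slot, jittered) so that
    genebodies never overlap; strands alternate with random flips.
    """
    rng = np.random.default_rng([seed, 101])
    chroms = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
    per_chrom = int(np.ceil(n_genes / n_chroms))
    rows = []
    gid = 0
    for chrom in chroms:
        slot = chrom_size // (per_chrom + 1)
        for j in range(per_chrom):
            if gid >= n_genes:
                break
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            length = min(length, slot - 2000)
            base = (j + 1) * slot
            start = base + int(rng.integers(0, max(1, slot - length - 1000)))
            start = min(start, chrom_size - length - 1)
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                {
                    "gene_id": f"gene{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": start if strand == "+" else end,
                }
            )
            gid += 1
    return ToyGenome(chroms, pd.DataFrame(rows, columns=GENE_COLUMNS))
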