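"""Simulation configuration: the study conditions every generator obeys."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class SimulationConfig:
    """Parameters of the synthetic kidney/tumor cohort.

    One fixed ``seed`` makes every generated artifact bit-reproducible;
    each generator derives an independent substream from it.  Defaults are
    desk-scale (a 2 x 5 Mb toy genome finishes in well under a minute) while
    preserving the statistical structure the pipeline assumes: nucleosomal
    insert-size periodicity for genuine cells, disjoint type-specific peak
    sets, bulk tumors dominated by one originating cell type, and a clinical
    (CIMP-like) label concentrated in one expression subgroup of a
    255-sample cohort (41 of them in the host subgroup, 8 labeled).
    """

    seed: int = 0

    # --- cell population ---
    cells_per_type: tuple[int, ...] = (200, 200, 200)
    n_background: int = 300

    # --- peak landscape ---
    n_peaks: int = 2000
    peak_width: int = 500
    specific_peaks_per_type: int = 150
    genebody_specific_fraction: float = 0.7  # share of specific peaks inside marker genebodies
    markers_per_type: int = 25
    n_housekeeping: int = 500

    # --- fragment generation ---
    depth_meanlog: float = math.log(8000.0)
    depth_sdlog: float = 0.3
    bg_depth_meanlog: float = math.log(600.0)
    bg_depth_sdlog: float = 0.5
    nucleosome_period: int = 200
    periodic_fraction: float = 0.5
    bg_periodic_fraction: float = 0.0
    tss_fraction: float = 0.25
    bg_tss_fraction: float = 0.05
    peak_fraction: float = 0.45  # genuine-cell fragments targeted at accessible peaks
    max_insert: int = 900

    # --- peak-by-cell accessibility probabilities ---
    p_specific: float = 0.6
    p_offtarget: float = 0.05
    p_housekeeping: float = 0.3

    # --- bulk tumors ---
    tumor_origins: tuple[int, ...] = (0, 1)     # indices into cell types
    tumors_per_origin: tuple[int, ...] = (30, 4)
    purity: float = 0.8
    tumor_depth: int = 200_000
    n_private_peaks: int = 50
    private_read_fraction: float = 0.05

    # --- bulk expression cohort ---
    n_samples: int = 255
    subgroup_size: int = 41          # a2-like host subgroup
    n_cimp: int = 8                  # labeled samples, all placed in the host subgroup
    expr_log2fc: float = 2.0
    expr_sdlog: float = 0.4
    expr_baseline_meanlog: float = math.log(50.0)
    expr_baseline_sdlog: float = 1.0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("cell counts must be >= 1")
        if not (0.5 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0.5, 1] for an identifiable origin")
        if self.n_cimp > self.subgroup_size:
            raise ValueError("CIMP count exceeds host subgroup size")
        if len(self.tumor_origins) != len(self.tumors_per_origin):
            raise ValueError("tumor_origins and tumors_per_origin must align")

    @property
    def n_celltypes(self) -> int:
        return len(self.cells_per_type)

    @property
    def celltype_names(self) -> list[str]:
        return [f"type{t}" for t in range(self.n_celltypes)]

    def substream(self, *key: int):
        """Deterministic child RNG for one generator."""
        import numpy as np

        return np.random.default_rng([self.seed, *key])


def small_config(seed: int = 0) -> SimulationConfig:
    """A reduced cohort for fast end-to-end runs (fewer cells, same structure)."""
    return SimulationConfig(
        seed=seed,
        cells_per_type=(90, 90),
        n_background=140,
        n_peaks=1200,
        specific_peaks_per_type=100,
        markers_per_type=20,
        n_housekeeping=500,
        depth_meanlog=math.log(6000.0),
        tumor_origins=(0, 1),
        tumors_per_origin=(24, 8),
    )
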