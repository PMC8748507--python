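"""Shared fixtures: one default synthetic cohort, simulated once per session."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from origin_atlas.config import SimulationConfig, small_config
from origin_atlas.genome import toy_genome
from origin_atlas.simulate import (
    peak_layout,
    simulate_fragments,
    simulate_peak_matrix,
)

warnings.filterwarnings("ignore", message="requested .* variable peaks")


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def fragments_and_labels(genome, default_config):
    return simulate_fragments(genome, default_config)


@pytest.fixture(scope="session")
def qc_table(genome, fragments_and_labels):
    from origin_atlas import qc

    frags, _ = fragments_and_labels
    return qc.barcode_qc_table(frags, genome)


@pytest.fixture(scope="session")
def peak_adata(genome, default_config):
    return simulate_peak_matrix(genome, default_config)


@pytest.fixture(scope="session")
def layout(genome, default_config):
    return peak_layout(genome, default_config)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One completed reduced-cohort pipeline run, shared across tests."""
    from origin_atlas.pipeline import PipelineConfig, run_pipeline, stage_seed

    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(outdir=str(outdir), seed=7)
    cfg.sim = small_config(seed=stage_seed(7, "simulate"))
    manifest = run_pipeline(cfg)
    return outdir, cfg, manifest
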