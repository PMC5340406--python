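from dataclasses import replace

import numpy as np
import pytest

from autozyg import ROHParams, SimConfig, build_reference, simulate_bundle

# reduced-scale configuration for fast unit tests; cohort counts shrink too
SMALL_CONFIG = SimConfig(
    n_contigs=2,
    contig_length_bp=600_000,
    n_array_snps_per_contig=400,
    n_genes=4,
    planted_roh=("chr1", 100_000, 300_000),
    n_cases=3,
    n_population_controls=8,
    n_panel_controls=6,
    n_population_carriers=2,
    background_variant_rate=2e-4,
    genotyping_error_rate=0.0,
    missing_rate=0.0,
    seed=7,
)

# ROH parameters scaled to the small fixture's 200 kb planted interval
SMALL_ROH_PARAMS = ROHParams(
    window_snps=20,
    max_het_per_window=1,
    max_missing_per_window=2,
    window_hit_threshold=0.05,
    min_segment_snps=30,
    min_segment_kb=50.0,
    min_density_kb_per_snp=50.0,
    max_gap_kb=1000.0,
)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-scale study (study-condition defaults, seed 1)."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_reference():
    return build_reference(SimConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
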