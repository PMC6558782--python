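"""Shared fixtures: small truth-known simulated datasets."""

import pytest

from mapanchor import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A compact cross: 2 chromosomes, 8 scaffolds, default noise levels."""
    return SimulationConfig(
        n_chromosomes=2,
        chromosome_length_bp=120_000,
        n_scaffolds_per_chromosome=4,
        n_individuals=80,
        markers_per_scaffold=3,
        genetic_length_cM=120.0,
        n_transcripts=8,
        n_ssrs=6,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_ds(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Same shape as small_config with every perturbation switched off."""
    return SimulationConfig(
        n_chromosomes=2,
        chromosome_length_bp=120_000,
        n_scaffolds_per_chromosome=4,
        n_individuals=120,
        markers_per_scaffold=3,
        genetic_length_cM=120.0,
        missing_rate=0.0,
        error_rate=0.0,
        distorted_fraction=0.0,
        non_aabb_fraction=0.0,
        n_transcripts=8,
        n_ssrs=6,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def clean_ds(clean_config):
    return simulate_dataset(clean_config)
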