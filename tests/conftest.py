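"""Shared fixtures: the reference catalog and discovery scenarios."""

from __future__ import annotations

import pytest

from dinosmrna.catalog import load_reference_catalog
from dinosmrna.discovery import discover_smrnas
from dinosmrna.synthio import (
    SimulationConfig,
    plant_genome,
    simulate_smrna_reads,
)


@pytest.fixture(scope="session")
def reference_catalog():
    return load_reference_catalog()


def build_discovery_scenario(seed: int = 3, modify=None):
    """A 21-precursor genome + reads, optionally with one degraded
    precursor spec; returns (config, genome result, read sim)."""
    config = SimulationConfig(rng_seed=seed)
    specs = config.default_precursor_specs()
    if modify is not None:
        modify(specs[5])
    config.precursor_specs = specs
    genome_res = plant_genome(config)
    reads = simulate_smrna_reads(genome_res.truth, config, genome_res.genome)
    return config, genome_res, reads


@pytest.fixture(scope="session")
def base_scenario():
    return build_discovery_scenario()


@pytest.fixture(scope="session")
def base_records(base_scenario):
    _, genome_res, reads = base_scenario
    return discover_smrnas(reads.alignments, genome_res.genome)
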