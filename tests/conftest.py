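"""Shared fixtures: small scaled genomes and panels keep tests fast while
full-scale objects are reserved for the pipeline-level checks."""

from __future__ import annotations

import numpy as np
import pytest

from roughmap.genome import build_default_genome, make_snp_panel
from roughmap.simulate import (
    default_causal_loci,
    default_phenotype_model,
    founder,
    rough_founder_segregant,
)


@pytest.fixture(scope="session")
def genome():
    return build_default_genome(scale=1.0)


@pytest.fixture(scope="session")
def genome_small():
    return build_default_genome(scale=0.1)


@pytest.fixture(scope="session")
def panel(genome):
    from roughmap.simulate import sga_marker_loci

    include = list(default_causal_loci(genome).values()) + [
        (c, p) for c, p, _ in sga_marker_loci(genome)
    ]
    return make_snp_panel(genome, 5000, seed=11, include=include)


@pytest.fixture(scope="session")
def panel_small(genome_small):
    return make_snp_panel(genome_small, 800, seed=12)


@pytest.fixture(scope="session")
def model():
    return default_phenotype_model()


@pytest.fixture(scope="session")
def causal_loci(genome):
    return default_causal_loci(genome)


@pytest.fixture(scope="session")
def by_founder(genome):
    return founder("BY", genome)


@pytest.fixture(scope="session")
def s3_founder(genome):
    return founder("3S", genome)


@pytest.fixture(scope="session")
def rough_segregant(genome):
    return rough_founder_segregant(genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
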