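"""Shared synthetic study sets, built once per session."""

import pytest

from spsr.fixtures import FixtureSpec, build_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Three homogeneous genomes, three EC categories, 2 SPs per gene."""
    spec = FixtureSpec(
        n_genomes=3,
        genome_length_nt=8_000,
        genes_per_ec={"6.1.1.1": 3, "1.1.1.1": 5, "2.7.7.7": 4},
        sps_per_gene=2,
        seed=11,
    )
    return build_fixture(spec)


@pytest.fixture(scope="session")
def taxon_fixture():
    """Two genomes from different phyla with phylum-specific TSP sets."""
    spec = FixtureSpec(
        n_genomes=2,
        genome_length_nt=8_000,
        genes_per_ec={"6.1.1.3": 4, "6.1.1.4": 4},
        sps_per_gene=2,
        taxon_assignment={0: "Proteobacteria", 1: "Firmicutes"},
        seed=7,
    )
    return build_fixture(spec)
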