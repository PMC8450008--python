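"""Shared fixtures: one small synthetic genome collection per session."""

from __future__ import annotations

import pytest

from struoforge.fixtures import FixtureSpec, synth_genomes, synth_reference


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(
        n_genomes=4,
        contigs_per_genome=1,
        contig_len=6_000,
        genes_per_genome=3,
        gene_len=600,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_collection(small_spec):
    """(contig sets, truth table, genome records) for a 4-genome fixture."""
    return synth_genomes(small_spec)


@pytest.fixture(scope="session")
def small_reference(small_collection):
    _, truth, _ = small_collection
    return synth_reference(truth, mutation_rate=0.0, seed=7)
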