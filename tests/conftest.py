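"""Shared fixtures: tiny hand-built genomes and one reusable simulated
compendium (fixed seed, module cached)."""
from __future__ import annotations

import numpy as np
import pytest

from selmap.compendium import Compendium, FamilyInfo, GeneRecord, Genome


def make_genome(genome_id: str, genes, replicon: str | None = None,
                species: str | None = None, lineage=(), habitat="unknown") -> Genome:
    """Build a genome from (gene_id, start, end, strand, families) tuples."""
    replicon = replicon or f"{genome_id}_chr"
    records = [GeneRecord(genome_id=genome_id, replicon_id=replicon, gene_id=gid,
                          start=start, end=end, strand=strand, families=set(fams))
               for gid, start, end, strand, fams in genes]
    g = Genome(genome_id=genome_id, species=species or genome_id,
               lineage=tuple(lineage), habitat=habitat,
               replicons={replicon: records})
    g.sort_and_rank()
    return g


def spaced_genome(genome_id: str, families_by_rank: dict[int, set], n_genes: int,
                  **kwargs) -> Genome:
    """Genome of ``n_genes`` evenly spaced genes with families at given ranks."""
    genes = []
    for k in range(n_genes):
        start = 1 + 1000 * k
        genes.append((f"{genome_id}_g{k:03d}", start, start + 899, "+",
                      families_by_rank.get(k, set())))
    return make_genome(genome_id, genes, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def sim_default():
    """One default simulation, shared across tests (read-only)."""
    from selmap.simulate import SimConfig, simulate_compendium
    config = SimConfig(seed=1)
    comp, truth = simulate_compendium(config)
    return config, comp, truth
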