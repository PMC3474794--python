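import numpy as np
import pytest

from icmhost.synthetic import CommunitySpec, generate_community
from icmhost.icm import train_model_set
from icmhost.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def tree():
    """Hand-built taxonomy exercising every query path.

    Phylum A has an order with two families; genus A1a has two species
    plus a species hanging under an unranked clade; the lineage of
    phylum A has no class node.  Phylum B is a plain ladder.
    """
    nodes = [
        TaxonNode(1, 1, "no_rank", "root"),
        TaxonNode(10, 1, "phylum", "PhylumA"),
        TaxonNode(11, 10, "order", "OrderA"),
        TaxonNode(12, 11, "family", "FamilyA1"),
        TaxonNode(13, 12, "genus", "GenusA1a"),
        TaxonNode(14, 13, "species", "SpeciesA1a-1"),
        TaxonNode(15, 13, "species", "SpeciesA1a-2"),
        TaxonNode(16, 12, "genus", "GenusA1b"),
        TaxonNode(17, 16, "species", "SpeciesA1b-1"),
        TaxonNode(18, 11, "family", "FamilyA2"),
        TaxonNode(19, 18, "genus", "GenusA2a"),
        TaxonNode(20, 19, "species", "SpeciesA2a-1"),
        TaxonNode(21, 13, "no_rank", "unranked clade"),
        TaxonNode(22, 21, "species", "SpeciesA1a-3"),
        TaxonNode(30, 1, "phylum", "PhylumB"),
        TaxonNode(31, 30, "order", "OrderB"),
        TaxonNode(32, 31, "family", "FamilyB1"),
        TaxonNode(33, 32, "genus", "GenusB1a"),
        TaxonNode(34, 33, "species", "SpeciesB1a-1"),
    ]
    return TaxonomyTree(nodes)


@pytest.fixture(scope="session")
def small_community():
    """A fast community: 2 phyla x 2 genera x 1 species, 120 kb genomes
    (long enough to cut one >100 kb scaffold each), 20 phages."""
    spec = CommunitySpec(
        n_phyla=2,
        genera_per_phylum=2,
        species_per_genus=1,
        genome_length=120_005,
        composition_order=2,
        divergence=0.2,
        phage_length=8_000,
        epsilon=0.1,
        n_phages=20,
        scaffolds_per_genome=1,
        scaffold_length=100_001,
        seed=7,
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def small_models(small_community):
    """One model per genus of the small community (K=4 keeps it quick)."""
    com = small_community
    pairs = [(g, com.genome_taxids[g.id]) for g in com.genomes]
    return train_model_set(
        pairs, pooling="node", pool_rank="genus", tree=com.taxonomy,
        K=4, alpha=1.0, C=50,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
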