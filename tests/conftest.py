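import numpy as np
import pytest

from rbclassify.index import build_index, build_text
from rbclassify.synthetic import SyntheticConfig, generate_database
from rbclassify.taxonomy import TaxonomyTree


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def toy_tree():
    # root 1 -> domain 2 -> species 100, 101 -> strains
    parents = {1: 1, 2: 1, 100: 2, 101: 2, 1000: 100, 1001: 100, 1100: 101}
    ranks = {1: "no rank", 2: "superkingdom", 100: "species", 101: "species",
             1000: "strain", 1001: "strain", 1100: "strain"}
    return TaxonomyTree(parents, ranks)


@pytest.fixture(scope="session")
def small_db():
    """Deterministic 2-species x 2-strain database with retained text."""
    cfg = SyntheticConfig(seed=11, base_genome_length=400, n_species=2, n_strains=2)
    syn = generate_database(cfg)
    sdb = build_text(syn.sequences, syn.id_map)
    return syn, sdb


@pytest.fixture(scope="session")
def small_index(small_db):
    syn, sdb = small_db
    idx, sa = build_index(sdb, keep_sa=True)
    return syn, sdb, idx, sa


@pytest.fixture(scope="session")
def small_taxonomy(small_db):
    syn, _ = small_db
    return TaxonomyTree(
        {t: v[0] for t, v in syn.taxonomy_nodes.items()},
        {t: v[1] for t, v in syn.taxonomy_nodes.items()},
        syn.taxonomy_names,
    )
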