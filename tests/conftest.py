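import numpy as np
import pytest

from scatdiet import assign as assign_mod
from scatdiet import simdata

# a small but rank-complete taxonomy used across assignment tests
TAXONOMY_ROWS = [
    # species, genus, family, order, class
    ("Niviventer confucianus", "Niviventer", "Muridae", "Rodentia", "Mammalia"),
    ("Niviventer excelsior", "Niviventer", "Muridae", "Rodentia", "Mammalia"),
    ("Apodemus draco", "Apodemus", "Muridae", "Rodentia", "Mammalia"),
    ("Eothenomys chinensis", "Eothenomys", "Cricetidae", "Rodentia", "Mammalia"),
    ("Ochotona curzoniae", "Ochotona", "Ochotonidae", "Lagomorpha", "Mammalia"),
    ("Ochotona thibetana", "Ochotona", "Ochotonidae", "Lagomorpha", "Mammalia"),
    ("Mustela erminea", "Mustela", "Mustelidae", "Carnivora", "Mammalia"),
    ("Mustela sibirica", "Mustela", "Mustelidae", "Carnivora", "Mammalia"),
    ("Tragopan temminckii", "Tragopan", "Phasianidae", "Galliformes", "Aves"),
    ("Gallus gallus", "Gallus", "Phasianidae", "Galliformes", "Aves"),
    ("Hirundo rustica", "Hirundo", "Hirundinidae", "Passeriformes", "Aves"),
]


@pytest.fixture(scope="session")
def taxonomy() -> assign_mod.Taxonomy:
    rows = [
        dict(zip(("species", "genus", "family", "order", "class_name"), r))
        for r in TAXONOMY_ROWS
    ]
    return assign_mod.Taxonomy(rows)


@pytest.fixture(scope="session")
def small_pool():
    return simdata.random_taxa_pool(6, seed=11)


@pytest.fixture(scope="session")
def refdb(small_pool):
    return simdata.generate_reference_db(small_pool, seed=11)


@pytest.fixture(scope="session")
def noise_free_run(small_pool):
    cfg = simdata.SimConfig(
        taxa_pool=small_pool,
        taxa_per_sample_range=(1, 4),
        n_samples=6,
        reads_per_sample=400,
        per_base_error_rate=0.0,
        tag_jump_rate=0.0,
        contaminant_rate=0.0,
        blocking_efficiency=1.0,
        seed=7,
    )
    return simdata.simulate_run(cfg)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
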