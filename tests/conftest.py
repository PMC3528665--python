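import numpy as np
import pytest

from haloriscan.genome_io import read_seed_panel
from haloriscan.synthetic_data import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def seed_panel():
    return read_seed_panel()


@pytest.fixture(scope="session")
def small_genome():
    """One compact genome mirroring the 6/4/1 initiator split across a
    chromosome, minichromosome and megaplasmid."""
    spec = SyntheticSpec(
        n_genomes=1,
        replicons=(
            ("chromosome", 80_000, "circular"),
            ("minichromosome", 60_000, "circular"),
            ("megaplasmid", 40_000, "circular"),
        ),
        n_cdc6=(6, 4, 1),
        decoy_gene_count=15,
        seed=11,
    )
    replicons, truth = generate_genome(spec, 0)
    return spec, replicons, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
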