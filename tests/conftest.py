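import numpy as np
import pandas as pd
import pytest

import emslink as el
from emslink.simulate import MUTATION_COLUMNS


@pytest.fixture(scope="session")
def small_catalogue():
    return el.uniform_gene_catalogue(20, 10)


@pytest.fixture(scope="session")
def small_config(small_catalogue):
    return el.SimulationConfig(
        n_lines=50, genes=small_catalogue, mean_mutations_per_line=15.0, seed=11
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    return el.simulate_genotypes(small_config)


def make_table(records):
    """Mutation table from (line, chrom, pos, ref, alt, gene, impact, qual, depth)."""
    return pd.DataFrame(records, columns=MUTATION_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
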