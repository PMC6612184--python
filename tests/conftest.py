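import numpy as np
import pytest
from hypothesis import settings

from traitscope._schema import Schema

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from traitscope.synthetic_data import SimulationSpec, gen_trait_database


@pytest.fixture(scope="session")
def schema():
    return Schema()


@pytest.fixture(scope="session")
def small_db_pair():
    """Two modest synthetic databases with the default (study-like) effect sizes."""
    spec = SimulationSpec(n_taxa=(120, 180), seed=42)
    db_a, db_b, truth = gen_trait_database(spec)
    return db_a, db_b, truth


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
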