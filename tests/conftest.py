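import numpy as np
import pytest

from mblsplice import formats_io as fio
from mblsplice import synthetic_data as synth

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across tests."""
    cfg = synth.SimulationConfig(seed=42, n_genes=60, n_conserved_genes=10,
                                 n_go_categories=10, go_category_size=8)
    return synth.simulate_all(cfg)


@pytest.fixture()
def toy_tree():
    return fio.read_newick("(R:1,(A:1,B:1):1);")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
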