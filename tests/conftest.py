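import numpy as np
import pytest

from tdnascout.reference_model import TDNARegion, linearize_plasmid
from tdnascout.simulate import random_host_genome, random_plasmid

WRAP = 150
# T-DNA interval in linearized coordinates (wrap + vector-local position)
TDNA_START = WRAP + 6392
TDNA_END = WRAP + 10291


@pytest.fixture(scope="session")
def plasmid():
    return random_plasmid(13_600, seed=1202)


@pytest.fixture(scope="session")
def linref(plasmid):
    return linearize_plasmid(plasmid, WRAP)


@pytest.fixture(scope="session")
def tdna():
    return TDNARegion(TDNA_START, TDNA_END)


@pytest.fixture(scope="session")
def small_host():
    return random_host_genome({"chr1": 50_000}, seed=1101)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_915)
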