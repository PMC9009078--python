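import numpy as np
import pytest

import embedshield as es
from embedshield.crystal import LatticeCell
from embedshield.synthdata import ToyCrystalParams


@pytest.fixture(scope="session")
def p1_params():
    return ToyCrystalParams(spacegroup="P1", seed=0)


@pytest.fixture(scope="session")
def p21_params():
    return ToyCrystalParams(spacegroup="P21", seed=1)


@pytest.fixture(scope="session")
def p1_crystal(p1_params):
    return es.make_toy_crystal(p1_params)


@pytest.fixture(scope="session")
def p21_crystal(p21_params):
    return es.make_toy_crystal(p21_params)


@pytest.fixture(scope="session")
def p21_cluster(p21_crystal, p21_params):
    charges = es.ChargeSet(
        dict(enumerate(p21_params.charges)), total_charge=0.0
    )
    return es.build_cluster(p21_crystal, cutoff=3.0, n=3, charges=charges)


@pytest.fixture(scope="session")
def benchmark_tables():
    return es.load_benchmark_tables()
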