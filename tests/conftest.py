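import numpy as np
import pytest

from mclig.compound import Compound, benzene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def benzene_c():
    return benzene()


#: structurally diverse seed molecules for fuzz walks
DIVERSE_SEEDS = [
    "C", "CC", "CCO", "c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1cc[nH]c1",
    "CC(=O)Nc1ccc(O)cc1", "c1ccc2ccccc2c1", "CC(C)Cc1ccc(C)cc1",
    "OCC1OC(O)C(O)C(O)C1O", "c1ccc(-c2ccccc2)cc1", "CN1CCCC1",
    "O=C1NC(=O)C(=Cc2ccccc2)S1", "Clc1ccccc1Br", "CSc1ccccc1",
    "CC1=CC(=O)CC(C)(C)C1", "c1cnc2[nH]ccc2c1", "CCOC(=O)c1ccccc1",
    "FC(F)(F)c1ccccc1",
]


@pytest.fixture(scope="session")
def diverse_compounds():
    return [Compound.from_smiles(s) for s in DIVERSE_SEEDS]
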