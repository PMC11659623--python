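import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mixodor.chem_features import canonicalize_molecule
from mixodor.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def alcohol_pool():
    """Four n-alcohols: every pair shares at least a C-C-O fragment."""
    smiles = {"eth": "CCO", "prop": "CCCO", "but": "CCCCO", "pent": "CCCCCO"}
    return [canonicalize_molecule(s, molecule_id=k) for k, s in smiles.items()]


@pytest.fixture(scope="session")
def default_dataset():
    """One study-shaped synthetic dataset, shared across read-only tests."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
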