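import numpy as np
import pytest

from allonet.model_io import ATOM_COLUMNS, AtomicModel
from allonet.synthetic import make_toy_crystal, benchmark_scenario

import pandas as pd


@pytest.fixture(scope="session")
def toy_model() -> AtomicModel:
    return make_toy_crystal(n_residues=15, seed=42)


@pytest.fixture(scope="session")
def scenario():
    """One frozen benchmark synthetic study used by several test modules."""
    return benchmark_scenario(seed=3)


def tiny_model(positions, elements=None, resnums=None, resnames=None, cell=(10, 10, 10, 90, 90, 90)):
    """Hand-built model from bare coordinates, for closed-form fixtures."""
    n = len(positions)
    elements = elements or ["C"] * n
    resnums = resnums or list(range(1, n + 1))
    resnames = resnames or ["ALA"] * n
    rows = [
        ("A", resnums[i], resnames[i], f"X{i}", "", elements[i], *positions[i], 1.0)
        for i in range(n)
    ]
    return AtomicModel(pd.DataFrame(rows, columns=ATOM_COLUMNS), cell=cell)
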