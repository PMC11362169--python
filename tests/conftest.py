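import numpy as np
import pandas as pd
import pytest

import hdxconf as hc


@pytest.fixture(scope="session")
def hinge_pair():
    """Toy two-helix structures with a known 25-degree hinge about z."""
    return hc.make_toy_hinge_structures(12, 25.0, (0.0, 0.0, 1.0), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-state simulated HDX dataset with truth (length 120)."""
    model, truth = hc.two_state_exchange_model(length=120, frac_affected=0.2,
                                               delta_logpf=1.0, seed=5)
    pmap = hc.generate_peptide_map(model.sequence, seed=5)
    table = hc.simulate_uptake_table(model, pmap, seed=5)
    return model, pmap, table, truth


def toy_structure(coords, atoms=None, chain="A", resname="GLY"):
    """Ad-hoc structure from bare coordinates (one atom per residue unless
    atom names are given)."""
    rows = []
    for i, xyz in enumerate(coords):
        name = atoms[i] if atoms else "CA"
        resnum = i + 1 if atoms is None else 1
        rows.append((chain, resnum, resname, name, name[0], *xyz))
    df = pd.DataFrame(rows, columns=["chain", "resnum", "resname", "atom",
                                     "element", "x", "y", "z"])
    return hc.StructureModel(df)


@pytest.fixture
def make_structure():
    return toy_structure


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
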