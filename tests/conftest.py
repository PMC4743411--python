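import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_molecules():
    """Name -> SMILES for hand-checkable molecules."""
    return {
        "methane": "C",
        "ethane": "CC",
        "propane": "CCC",
        "butane": "CCCC",
        "hexane": "CCCCCC",
        "methanol": "CO",
        "water": "O",
        "benzene": "c1ccccc1",
        "toluene": "Cc1ccccc1",
        "naphthalene": "c1ccc2ccccc2c1",
        "cyclohexane": "C1CCCCC1",
        "quinoline": "c1ccc2ncccc2c1",
    }


def random_alkane_tree(rng, n_atoms: int):
    """A random tree on n carbon atoms as an RDKit molecule (random alkane)."""
    from rdkit import Chem

    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom("C"))
    for i in range(1, n_atoms):
        mol.AddAtom(Chem.Atom("C"))
        parent = int(rng.integers(0, i))
        # keep carbon valence legal: re-draw the parent until it has < 4 bonds
        while mol.GetAtomWithIdx(parent).GetDegree() >= 4:
            parent = int(rng.integers(0, i))
        mol.AddBond(parent, i, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out
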