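import numpy as np
import pytest

from varstab.simulate import SyntheticConfig, generate_cohort, generate_toy_structure
from varstab.structures import Atom, ProteinStructure, Residue, read_pdb


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic two-group cohort at the default study conditions."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def toy_helix():
    """Single-chain 20-residue toy helix structure."""
    return read_pdb(generate_toy_structure(20, ("A",), seed=7), "helix")


@pytest.fixture(scope="session")
def toy_complex():
    """Two toy helices in contact (chain B occludes part of chain A)."""
    return read_pdb(generate_toy_structure(20, ("A", "B"), seed=7), "complex")


def single_atom_structure(element="C", radius=1.70, coords=(0.0, 0.0, 0.0)):
    atom = Atom(name=element, element=element, coords=np.array(coords),
                radius=radius)
    res = Residue(seq_number=1, aa="A", atoms=[atom])
    return ProteinStructure(structure_id="one", chains={"A": [res]})


def atoms_structure(coords_list, radius=1.70):
    """Structure with one carbon atom per residue at the given coordinates."""
    residues = [
        Residue(seq_number=i + 1, aa="A",
                atoms=[Atom(name="C", element="C",
                            coords=np.asarray(c, dtype=float), radius=radius)])
        for i, c in enumerate(coords_list)
    ]
    return ProteinStructure(structure_id="pts", chains={"A": residues})
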