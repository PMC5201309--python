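import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from grindqsar.chem_io import Atom, AtomType, Molecule, molecule_from_rdkit


def embedded(smiles: str, name: str, seed: int = 7) -> Molecule:
    """A 3D-embedded molecule from SMILES (with explicit hydrogens)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    return molecule_from_rdkit(mol, name)


@pytest.fixture(scope="session")
def benzene() -> Molecule:
    return embedded("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def methanol() -> Molecule:
    return embedded("CO", "methanol")


@pytest.fixture(scope="session")
def pyridine() -> Molecule:
    return embedded("c1ccncc1", "pyridine")


@pytest.fixture(scope="session")
def acetone() -> Molecule:
    return embedded("CC(=O)C", "acetone")


@pytest.fixture()
def water_sdf(tmp_path):
    path = tmp_path / "water.sdf"
    path.write_text(
        "water\n     RDKit          3D\n\n"
        "  3  2  0  0  0  0  0  0  0  0999 V2000\n"
        "    0.0000    0.0000    0.1173 O   0  0  0  0  0  0  0  0  0  0  0  0\n"
        "    0.0000    0.7572   -0.4692 H   0  0  0  0  0  0  0  0  0  0  0  0\n"
        "    0.0000   -0.7572   -0.4692 H   0  0  0  0  0  0  0  0  0  0  0  0\n"
        "  1  2  1  0\n  1  3  1  0\nM  END\n$$$$\n"
    )
    return path


def single_atom_molecule(element: str = "C", charge: float = 0.0,
                         atom_type: AtomType = AtomType.HYDROPHOBE) -> Molecule:
    return Molecule("single", [Atom(element, np.zeros(3), charge, atom_type)])
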