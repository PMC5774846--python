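import numpy as np
import pytest

from topomol import Atom, ComplexStructure, Molecule


@pytest.fixture
def chain_molecule() -> Molecule:
    """Linear three-atom chain A-B-C with unit bonds (|AC| = 2)."""
    coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
    atoms = [Atom(i + 1, "C", np.array(c, float)) for i, c in enumerate(coords)]
    return Molecule(atoms, [(0, 1), (1, 2)], "chain3")


@pytest.fixture
def methane_like() -> Molecule:
    """One carbon with four hydrogens, ligand role."""
    c = Atom(1, "C", np.zeros(3), charge=-0.4, role="ligand")
    hs = [
        Atom(2 + k, "H", np.array(v, float) * 1.09, charge=0.1, role="ligand")
        for k, v in enumerate([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
    ]
    return Molecule([c] + hs, [(0, k) for k in range(1, 5)], "methane")


@pytest.fixture
def small_complex() -> ComplexStructure:
    """Four protein carbons around two ligand oxygens, all charged."""
    prot = Molecule(
        [
            Atom(k + 1, "C", np.array(c, float), charge=0.1, role="protein")
            for k, c in enumerate([[4, 0, 0], [-4, 0, 0], [0, 4, 0], [0, -4, 0]])
        ],
        [],
        "prot",
    )
    lig = Molecule(
        [
            Atom(10, "O", np.array([0.7, 0, 0]), charge=-0.3, role="ligand"),
            Atom(11, "O", np.array([-0.7, 0, 0]), charge=-0.3, role="ligand"),
        ],
        [(0, 1)],
        "lig",
    )
    return ComplexStructure(prot, lig)
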