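import math

import numpy as np
import pytest

from topomol import (
    Atom,
    ComplexStructure,
    ElementSelection,
    Molecule,
    build_bond_graph,
    read_structure,
    select_atoms,
    truncate_binding_site,
    write_mol2,
    write_pdb,
)
from topomol.structures import ParseError

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
END
"""

MINIMAL_MOL2 = """\
@<TRIPOS>MOLECULE
tiny
3 2 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 C1    0.0000    0.0000    0.0000 C.3   1 MOL   -0.1000
      2 O1    1.4000    0.0000    0.0000 O.3   1 MOL   -0.4000
      3 N1    2.8000    0.0000    0.0000 N.3   1 MOL    0.5000
@<TRIPOS>BOND
     1     1     2 1
     2     2     3 1
"""


class TestReadStructure:
    def test_minimal_pdb_records(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        mol = read_structure(p)
        assert len(mol) == 2
        assert mol.bonds == []
        assert mol.elements == ["N", "C"]
        assert mol.atoms[0].role == "protein"
        np.testing.assert_allclose(mol.atoms[1].coords, [1.458, 0, 0])

    def test_minimal_mol2(self, tmp_path):
        p = tmp_path / "tiny.mol2"
        p.write_text(MINIMAL_MOL2)
        mol = read_structure(p)
        assert len(mol) == 3
        assert mol.bonds == [(0, 1), (1, 2)]
        assert mol.charges == [-0.1, -0.4, 0.5]
        assert mol.atoms[0].role == "ligand"
        assert mol.id == "tiny"

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_structure("/nonexistent/thing.pdb")

    def test_malformed_mol2_names_line(self, tmp_path):
        p = tmp_path / "bad.mol2"
        p.write_text("@<TRIPOS>ATOM\n1 C1 not-a-number 0 0 C\n")
        with pytest.raises(ParseError, match="bad.mol2:2"):
            read_structure(p)

    def test_roundtrip_mol2(self, tmp_path):
        atoms = [
            Atom(1, "C", np.array([0.0, 0, 0]), charge=-0.2),
            Atom(2, "Cl", np.array([1.7, 0, 0]), charge=0.2),
        ]
        mol = Molecule(atoms, [(0, 1)], "pair")
        path = tmp_path / "pair.mol2"
        write_mol2(mol, path)
        back = read_structure(path)
        assert back.elements == ["C", "Cl"]
        assert back.bonds == [(0, 1)]
        np.testing.assert_allclose(back.coords, mol.coords, atol=1e-4)
        np.testing.assert_allclose(back.charges, [-0.2, 0.2], atol=1e-4)

    def test_roundtrip_pdb(self, tmp_path):
        atoms = [Atom(k + 1, e, np.array([k * 2.0, 0, 0])) for k, e in enumerate("CNO")]
        path = tmp_path / "tri.pdb"
        write_pdb(Molecule(atoms, [], "tri"), path)
        back = read_structure(path)
        assert back.elements == ["C", "N", "O"]
        np.testing.assert_allclose(back.coords, [[0, 0, 0], [2, 0, 0], [4, 0, 0]], atol=1e-3)


class TestBondGraph:
    def test_chain_hops(self, chain_molecule):
        g = build_bond_graph(chain_molecule)
        assert g.hop_distance(0, 2) == 2
        assert g.hop_distance(0, 0) == 0

    def test_disconnected_unreachable(self):
        atoms = [Atom(1, "C", np.zeros(3)), Atom(2, "C", np.array([9.0, 0, 0]))]
        g = build_bond_graph(Molecule(atoms, []), mode="distance_cutoff")
        assert math.isinf(g.hop_distance(0, 1))

    def test_distance_cutoff_cc_bond(self):
        # 1.4 <= 1.3 * (0.76 + 0.76)
        atoms = [Atom(1, "C", np.zeros(3)), Atom(2, "C", np.array([1.4, 0, 0]))]
        g = build_bond_graph(Molecule(atoms, []), mode="distance_cutoff")
        assert g.hop_distance(0, 1) == 1

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            build_bond_graph(Molecule([], []), mode="distance_cutoff")

    def test_matches_bfs_oracle_on_random_graphs(self):
        # independent BFS oracle, hand-rolled
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 21))
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.15
            ]
            atoms = [Atom(k + 1, "C", rng.normal(size=3)) for k in range(n)]
            if not edges:
                continue
            g = build_bond_graph(Molecule(atoms, edges))
            adj = {k: set() for k in range(n)}
            for i, j in edges:
                adj[i].add(j)
                adj[j].add(i)
            for src in range(n):
                dist = {src: 0}
                frontier = [src]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in adj[u]:
                            if v not in dist:
                                dist[v] = dist[u] + 1
                                nxt.append(v)
                    frontier = nxt
                for dst in range(n):
                    expected = dist.get(dst, math.inf)
                    assert g.hop_distance(src, dst) == expected


class TestSelectAtoms:
    def test_single_element(self, methane_like):
        assert len(select_atoms(methane_like, ElementSelection.ligand("C"))) == 1
        assert select_atoms(methane_like, ElementSelection.ligand("N")) == []

    def test_complex_roles_preserved(self, small_complex):
        sel = ElementSelection.pair("C", "O")
        picked = select_atoms(small_complex, sel)
        assert len(picked) == 6
        assert [a.role for a in picked] == ["protein"] * 4 + ["ligand"] * 2

    def test_heavy_excludes_hydrogen(self, methane_like):
        heavy = ElementSelection(ligand_elements="heavy")
        assert len(select_atoms(methane_like, heavy)) == 1
        everything = ElementSelection(ligand_elements="all")
        assert len(select_atoms(methane_like, everything)) == 5

    def test_idempotent_and_monotone(self, small_complex):
        small = ElementSelection.pair("C", "O")
        bigger = ElementSelection.pair("CN", "CO")
        picked = select_atoms(small_complex, small)
        again = select_atoms(Molecule(picked, []), small)
        assert [a.serial for a in again] == [a.serial for a in picked]
        assert {a.serial for a in picked} <= {
            a.serial for a in select_atoms(small_complex, bigger)
        }

    def test_label_deterministic(self):
        sel = ElementSelection.pair("NC", "OC")
        assert sel.label == "CN-CO"
        assert ElementSelection.ligand("CNOSPFClBrIH").label == "CNOSPFClBrIH"


class TestTruncateBindingSite:
    def _cx(self, protein_x):
        prot = Molecule(
            [Atom(k + 1, "C", np.array([x, 0, 0]), role="protein")
             for k, x in enumerate(protein_x)],
            [],
        )
        lig = Molecule([Atom(99, "O", np.zeros(3), role="ligand")], [])
        return ComplexStructure(prot, lig)

    def test_cutoff_12(self):
        out = truncate_binding_site(self._cx([5.0, 20.0]), 12.0)
        assert len(out.protein) == 1
        assert len(out.ligand) == 1

    def test_large_cutoff_identity(self):
        out = truncate_binding_site(self._cx([5.0, 20.0]), 100.0)
        assert len(out.protein) == 2

    def test_tiny_cutoff_empty_protein(self):
        out = truncate_binding_site(self._cx([5.0, 20.0]), 1.0)
        assert len(out.protein) == 0

    def test_monotone_in_cutoff(self):
        xs = [2.0, 4.0, 8.0, 16.0]
        counts = [
            len(truncate_binding_site(self._cx(xs), c).protein)
            for c in (20, 10, 5, 3, 1)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            truncate_binding_site(self._cx([5.0]), 0.0)
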