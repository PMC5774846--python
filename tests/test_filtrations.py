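import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topomol import (
    Atom,
    FiltrationMatrix,
    KernelSpec,
    build_bond_graph,
    charge_density,
    correlation_matrix,
    electrostatic_matrix,
    electrostatic_value,
    euclidean_matrix,
    interactive_matrix,
    multilevel_matrix,
    rigidity_index,
)


def _atoms(coords, element="C", charge=None, role="ligand"):
    return [
        Atom(k + 1, element, np.array(c, float), charge=charge, role=role)
        for k, c in enumerate(coords)
    ]


class TestEuclidean:
    def test_pair(self):
        m = euclidean_matrix(_atoms([[0, 0, 0], [3, 0, 0]]))
        assert m.values[0, 1] == pytest.approx(3.0)

    def test_single_atom(self):
        m = euclidean_matrix(_atoms([[1, 2, 3]]))
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0

    def test_equilateral(self):
        pts = [[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]]
        m = euclidean_matrix(_atoms(pts))
        off = m.values[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 2.0)

    def test_symmetric_zero_diagonal_random(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = euclidean_matrix(rng.normal(size=(8, 3)))
            np.testing.assert_allclose(m.values, m.values.T)
            np.testing.assert_allclose(np.diag(m.values), 0)


class TestMultilevel:
    def test_bonded_pair_excluded(self):
        atoms = _atoms([[0, 0, 0], [1.5, 0, 0]])
        from topomol import Molecule

        g = build_bond_graph(Molecule(atoms, [(0, 1)]))
        m = multilevel_matrix(atoms, g, level=1)
        assert m.excluded[0, 1]
        assert len(m.finite_edges()) == 0

    def test_chain_level1_only_ac(self, chain_molecule):
        g = build_bond_graph(chain_molecule)
        m = multilevel_matrix(chain_molecule.atoms, g, level=1)
        assert m.finite_edges() == [(2.0, 0, 2)]

    def test_chain_level2_all_excluded(self, chain_molecule):
        g = build_bond_graph(chain_molecule)
        m = multilevel_matrix(chain_molecule.atoms, g, level=2)
        assert m.finite_edges() == []

    def test_exclusion_nested_in_level(self, chain_molecule):
        g = build_bond_graph(chain_molecule)
        m1 = multilevel_matrix(chain_molecule.atoms, g, 1)
        m2 = multilevel_matrix(chain_molecule.atoms, g, 2)
        assert np.all(m2.excluded | ~m1.excluded)

    def test_level_zero_rejected(self, chain_molecule):
        g = build_bond_graph(chain_molecule)
        with pytest.raises(ValueError):
            multilevel_matrix(chain_molecule.atoms, g, level=0)


class TestInteractive:
    def test_single_cross_pair(self):
        atoms = _atoms([[0, 0, 0]], role="protein") + _atoms([[3, 0, 0]], role="ligand")
        m = interactive_matrix(atoms)
        assert m.finite_edges() == [(3.0, 0, 1)]

    def test_cross_pair_count(self):
        atoms = _atoms([[0, 0, 0], [1, 0, 0]], role="protein") + _atoms(
            [[0, 5, 0], [1, 5, 0]], role="ligand"
        )
        m = interactive_matrix(atoms)
        assert len(m.finite_edges()) == 4  # |A1| * |A2|

    def test_composition_with_electrostatic(self):
        atoms = _atoms([[0, 0, 0]], charge=0.4, role="protein") + _atoms(
            [[4, 0, 0]], charge=-0.4, role="ligand"
        )
        base = electrostatic_matrix(atoms, c=100)
        m = interactive_matrix(atoms, base=base)
        (value, i, j) = m.finite_edges()[0]
        assert value == pytest.approx(1 / (1 + math.exp(4)), rel=1e-6)

    def test_empty_partition_rejected(self):
        atoms = _atoms([[0, 0, 0], [1, 0, 0]], role="ligand")
        with pytest.raises(ValueError):
            interactive_matrix(atoms)


class TestCorrelation:
    def test_zero_distance(self):
        m = correlation_matrix(_atoms([[0, 0, 0], [0, 0, 1e-12]]))
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_half_at_eta(self):
        kernel = KernelSpec("lorentz", eta=2.0, nu=2.0)
        m = correlation_matrix(_atoms([[0, 0, 0], [2, 0, 0]]), kernel)
        assert m.values[0, 1] == pytest.approx(0.5)

    def test_excluded_set(self):
        atoms = _atoms([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        m = correlation_matrix(atoms, excluded_set=[2])
        assert m.excluded[0, 2] and m.excluded[1, 2] and not m.excluded[0, 1]

    def test_values_bounded_and_decreasing(self):
        kernel = KernelSpec("lorentz", eta=3.0, nu=3.0)
        d = np.linspace(0.1, 20, 50)
        phi = kernel.phi(d, 3.0)
        assert np.all(np.diff(phi) < 0)
        rng = np.random.default_rng(1)
        m = correlation_matrix(_atoms(rng.normal(size=(6, 3)) * 3))
        assert np.all(m.values >= 0) and np.all(m.values <= 1)


class TestElectrostatic:
    def test_neutral_is_half(self):
        assert electrostatic_value(5.0, 0.0, 0.3) == pytest.approx(0.5)

    def test_hand_values(self):
        assert electrostatic_value(4, 0.4, -0.4, 100) == pytest.approx(
            1 / (1 + math.exp(4)), rel=1e-9
        )
        assert electrostatic_value(4, 0.4, 0.4, 100) == pytest.approx(
            1 / (1 + math.exp(-4)), rel=1e-9
        )

    @settings(max_examples=60, derandomize=True)
    @given(
        q=st.floats(-1, 1),
        d=st.floats(0.5, 30),
    )
    def test_bounded_open_interval(self, q, d):
        v = electrostatic_value(d, q, 0.37, c=100)
        assert 0.0 <= v <= 1.0

    def test_monotone_in_charge_product(self):
        products = np.linspace(-0.5, 0.5, 21)
        vals = [electrostatic_value(3.0, p, 1.0, 100) for p in products]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matrix_all_zero_charges(self):
        m = electrostatic_matrix(_atoms([[0, 0, 0], [2, 0, 0]], charge=0.0))
        assert m.values[0, 1] == pytest.approx(0.5)
        assert m.axis_range == (0.0, 1.0)

    def test_missing_charge_names_atom(self):
        atoms = _atoms([[0, 0, 0]], charge=0.1) + _atoms([[1, 0, 0]])
        with pytest.raises(ValueError, match="serial 1"):
            electrostatic_matrix(atoms)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            electrostatic_value(0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            electrostatic_value(1.0, 0.1, 0.1, c=0.0)


class TestRigidityAndDensity:
    def test_isolated_atom(self):
        assert rigidity_index(_atoms([[0, 0, 0]]))[0] == 0.0

    def test_pair_at_eta(self):
        kernel = KernelSpec("lorentz", eta=2.0, nu=2.0)
        mu = rigidity_index(_atoms([[0, 0, 0], [2, 0, 0]]), kernel)
        np.testing.assert_allclose(mu, 0.5)

    def test_triangle_at_eta(self):
        pts = [[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]]
        kernel = KernelSpec("lorentz", eta=2.0, nu=2.0)
        np.testing.assert_allclose(rigidity_index(_atoms(pts), kernel), 1.0)

    def test_density_at_atom(self):
        atoms = _atoms([[0, 0, 0]], charge=1.0)
        assert charge_density(atoms, [0, 0, 0], eta=1.5) == pytest.approx(1.0)

    def test_density_decay(self):
        atoms = _atoms([[0, 0, 0]], charge=1.0)
        far = charge_density(atoms, [10.0, 0, 0], eta=1.0)
        assert far == pytest.approx(math.exp(-10), rel=1e-9)

    def test_density_cancellation(self):
        atoms = _atoms([[1, 0, 0]], charge=1.0) + _atoms([[-1, 0, 0]], charge=-1.0)
        assert charge_density(atoms, [0, 0, 0], eta=2.0) == pytest.approx(0.0, abs=1e-12)


class TestFiltrationMatrixContainer:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            FiltrationMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_tsv_roundtrip(self, tmp_path):
        values = np.array([[0.0, 1.5, 2.0], [1.5, 0.0, 9.0], [2.0, 9.0, 0.0]])
        excluded = np.zeros((3, 3), bool)
        excluded[1, 2] = excluded[2, 1] = True
        m = FiltrationMatrix(values, excluded, "multilevel(1)", (0.0, 12.0))
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = FiltrationMatrix.from_tsv(path)
        assert back.scheme == "multilevel(1)"
        assert back.axis_range == (0.0, 12.0)
        np.testing.assert_allclose(back.values[0], values[0])
        assert back.excluded[1, 2] and not back.excluded[0, 1]
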