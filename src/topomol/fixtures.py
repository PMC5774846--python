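"""Deterministic synthetic inputs for every stage of the pipeline.

These generators stand in for experimental protein structures, docked
small molecules and active/decoy screening libraries, so that the whole
package is exercisable without downloads:

* canonical point clouds (line, square, circle, tetrahedron, random) with
  oracle-known barcodes;
* "toy molecules": connected bond graphs with bond lengths in the
  1.3-1.8 Angstrom covalent range, elements drawn from a palette and
  Gasteiger-like partial charges that sum to a small net value;
* conformer pairs: bond topology preserved, coordinates jittered within a
  bounded displacement;
* screening sets: a rigid icosahedral pocket of protein-role atoms per
  target; *actives* receive complementary contacts (cross-role near-pairs
  at 2.8-3.5 Angstrom with opposite partial charges, scaled by an effect
  size), *decoys* receive randomized contacts. At effect 0 the two classes
  are exchangeable in distribution by construction.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import Atom, ComplexStructure, Molecule, write_mol2, write_pdb

#: Contact-distance draw for complementary (active) contacts, Angstrom.
ACTIVE_CONTACT_RANGE = (2.8, 3.5)
#: Contact-distance draw for randomized (decoy) contacts, Angstrom.
DECOY_CONTACT_RANGE = (3.8, 5.5)
#: Radius of the icosahedral pocket cage, Angstrom.
POCKET_RADIUS = 7.0
#: Number of cross-role contacts planted per compound.
N_CONTACTS = 3


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic input."""

    kind: str  # {"point_cloud", "toy_molecule", "conformer_pair", "screen_set"}
    seed: int = 0
    params: dict = field(default_factory=dict)


def generate(spec: FixtureSpec):
    dispatch = {
        "point_cloud": make_point_cloud,
        "toy_molecule": make_toy_molecule,
        "conformer_pair": make_conformer_pair,
        "screen_set": make_screen_set,
    }
    if spec.kind not in dispatch:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return dispatch[spec.kind](seed=spec.seed, **spec.params)


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------


def make_point_cloud(
    shape: str, n: int = 4, scale: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Canonical (n, 3) coordinate sets with oracle-known barcodes."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if shape == "line":
        pts = np.zeros((n, 3))
        pts[:, 0] = scale * np.arange(n)
    elif shape == "square":
        pts = scale * np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float
        )
    elif shape == "circle":
        angles = 2 * np.pi * np.arange(n) / n
        pts = np.stack(
            [scale * np.cos(angles), scale * np.sin(angles), np.zeros(n)], axis=1
        )
    elif shape == "tetrahedron":
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        pts = verts * (scale / np.linalg.norm(verts[0] - verts[1]))
    elif shape == "random":
        rng = np.random.default_rng(seed)
        pts = scale * rng.uniform(size=(n, 3))
    else:
        raise ValueError(f"unknown point-cloud shape {shape!r}")
    return pts


# ---------------------------------------------------------------------------
# Toy molecules and conformers
# ---------------------------------------------------------------------------


def make_toy_molecule(
    n_atoms: int = 10,
    element_palette: tuple[str, ...] = ("C", "C", "N", "O", "S"),
    seed: int = 0,
    mol_id: str | None = None,
) -> Molecule:
    """A connected random molecule with ligand roles and partial charges.

    Atoms are grown one bond at a time (random attachment point, bond
    length uniform in 1.3-1.8 Angstrom, direction resampled to keep
    non-bonded atoms at least 1.2 Angstrom apart). Charges are uniform
    draws recentred to a zero net charge.
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    bonds: list[tuple[int, int]] = []
    # compact growth: new atoms stay within ~2.4 A of the seed atom, the
    # typical gyration of a drug-like fragment
    for i in range(1, n_atoms):
        anchor = int(rng.integers(i))
        pos = None
        for attempt in range(96):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = coords[anchor] + rng.uniform(1.3, 1.8) * direction
            clashes = any(
                np.linalg.norm(cand - coords[j]) < 1.2
                for j in range(i)
                if j != anchor
            )
            if clashes:
                continue
            if np.linalg.norm(cand) <= 2.4 or attempt >= 64:
                pos = cand
                break
        if pos is None:  # crowded anchor: accept a clash-free long direction
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = coords[anchor] + 1.8 * direction
        coords.append(pos)
        bonds.append((anchor, i))
    elements = [str(rng.choice(element_palette)) for _ in range(n_atoms)]
    charges = rng.uniform(-0.5, 0.5, size=n_atoms)
    charges -= charges.mean()  # net charge ~ 0
    charges = np.clip(charges, -1.0, 1.0)
    atoms = [
        Atom(k + 1, elements[k], coords[k], charge=float(charges[k]), role="ligand")
        for k in range(n_atoms)
    ]
    return Molecule(atoms, bonds, mol_id or f"toy{seed}")


def perturb_conformation(mol: Molecule, magnitude: float, seed: int = 0) -> Molecule:
    """Jitter coordinates within a ball of radius *magnitude*; bonds unchanged."""
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    rng = np.random.default_rng(seed)
    atoms = []
    for atom in mol.atoms:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = magnitude * rng.uniform() ** (1.0 / 3.0)
        atoms.append(
            Atom(atom.serial, atom.element, atom.coords + radius * direction,
                 charge=atom.charge, role=atom.role)
        )
    return Molecule(atoms, list(mol.bonds), mol.id + "_conf")


def make_conformer_pair(
    n_atoms: int = 10, magnitude: float = 0.3, seed: int = 0
) -> tuple[Molecule, Molecule]:
    """A toy molecule and a bounded-jitter conformer of it."""
    mol = make_toy_molecule(n_atoms, seed=seed)
    return mol, perturb_conformation(mol, magnitude, seed=seed + 1)


# ---------------------------------------------------------------------------
# Screening sets
# ---------------------------------------------------------------------------


def _icosahedron(radius: float) -> np.ndarray:
    phi = (1 + math.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    return radius * verts / np.linalg.norm(verts[0])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def make_pocket(seed: int = 0, target_index: int = 0) -> Molecule:
    """A rigid icosahedral cage of protein-role atoms with partial charges."""
    rng = np.random.default_rng(seed + 7919 * target_index)
    coords = _icosahedron(POCKET_RADIUS) @ _random_rotation(rng).T
    elements = rng.choice(["C", "N", "O", "S"], size=12, p=[0.5, 0.2, 0.2, 0.1])
    # charge magnitudes bounded away from zero so complementarity is
    # expressible on the electrostatic filtration axis
    charges = rng.uniform(0.25, 0.5, size=12) * rng.choice([-1.0, 1.0], size=12)
    atoms = [
        Atom(k + 1, str(elements[k]), coords[k], charge=float(charges[k]), role="protein")
        for k in range(12)
    ]
    return Molecule(atoms, [], f"pocket{target_index}")


def _plant_contacts(
    pocket: Molecule, mol: Molecule, strength: float, rng: np.random.Generator
) -> Molecule:
    """Move ligand atoms toward selected pocket atoms and set contact charges.

    ``strength`` interpolates between the randomized decoy distribution
    (0) and fully complementary contacts (1); at 0 the transformation is
    label-independent, making classes exchangeable.
    """
    s = min(max(strength, 0.0), 1.0)
    atoms = [
        Atom(a.serial, a.element, a.coords.copy(), charge=a.charge, role="ligand")
        for a in mol.atoms
    ]
    # hydrogen-bond-like contacts pair polar (N/O) partners where available
    polar_pocket = [k for k, a in enumerate(pocket.atoms) if a.element in ("N", "O")]
    pool = polar_pocket if len(polar_pocket) >= N_CONTACTS else list(range(len(pocket)))
    pocket_idx = rng.choice(pool, size=N_CONTACTS, replace=False)
    used: set[int] = set()
    for pi in pocket_idx:
        p_atom = pocket.atoms[int(pi)]

        def _dist(k: int, a: Atom) -> float:
            if k in used:
                return np.inf
            penalty = 0.0 if a.element in ("N", "O") else 1e3
            return float(np.linalg.norm(a.coords - p_atom.coords)) + penalty

        li = int(np.argmin([_dist(k, a) for k, a in enumerate(atoms)]))
        used.add(li)
        d_decoy = rng.uniform(*DECOY_CONTACT_RANGE)
        d_active = rng.uniform(*ACTIVE_CONTACT_RANGE)
        d = (1 - s) * d_decoy + s * d_active
        direction = -p_atom.coords / np.linalg.norm(p_atom.coords)  # toward center
        atoms[li].coords = p_atom.coords + d * direction
        q_rand = rng.uniform(-0.5, 0.5)
        q_comp = -math.copysign(rng.uniform(0.3, 0.5), p_atom.charge)
        atoms[li].charge = float((1 - s) * q_rand + s * q_comp)
    return Molecule(atoms, list(mol.bonds), mol.id)


def make_screen_set(
    n_targets: int = 4,
    n_actives: int = 10,
    n_decoys: int = 30,
    effect: float = 1.0,
    seed: int = 0,
) -> list[tuple[ComplexStructure, str, str]]:
    """Synthetic screening library: ``(complex, target_id, label)`` records."""
    if effect < 0:
        raise ValueError("effect must be non-negative")
    rng = np.random.default_rng(seed)
    out: list[tuple[ComplexStructure, str, str]] = []
    for t in range(n_targets):
        pocket = make_pocket(seed=seed, target_index=t)
        for k in range(n_actives + n_decoys):
            label = "active" if k < n_actives else "decoy"
            mol = make_toy_molecule(
                int(rng.integers(8, 13)),
                seed=int(rng.integers(2**31)),
                mol_id=f"T{t}_{label}{k}",
            )
            centered = mol.coords - mol.coords.mean(axis=0)
            rot = _random_rotation(rng)
            for a, c in zip(mol.atoms, centered @ rot.T):
                a.coords = c
            strength = effect if label == "active" else 0.0
            docked = _plant_contacts(pocket, mol, strength, rng)
            out.append((ComplexStructure(pocket, docked), f"T{t}", label))
    return out


def write_screen_set(
    records: list[tuple[ComplexStructure, str, str]], out_dir: str | Path
) -> None:
    """Write pockets as PDB and compounds as Mol2, plus a labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen_targets: set[str] = set()
    lines = ["compound_id,target_id,label,mol2"]
    for cx, target, label in records:
        if target not in seen_targets:
            seen_targets.add(target)
            write_pdb(cx.protein, out_dir / f"{target}.pdb")
        name = f"{cx.ligand.id}.mol2"
        write_mol2(cx.ligand, out_dir / name)
        lines.append(f"{cx.ligand.id},{target},{label},{name}")
    (out_dir / "labels.csv").write_text("\n".join(lines) + "\n")
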