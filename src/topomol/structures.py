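"""Molecular structures, bond graphs, element selections and binding sites.

The in-memory model is deliberately small: an :class:`Atom` is a labelled
3-D point (element symbol, optional partial charge, protein/ligand role),
a :class:`Molecule` is an ordered atom list plus an undirected covalent
bond list, and a :class:`ComplexStructure` pairs a protein with a ligand.
Everything downstream (filtration matrices, persistence, features) consumes
these objects.

File formats: PDB is read and written through :mod:`gemmi`; TRIPOS Mol2
(the ligand format carrying partial charges and an explicit bond block) is
parsed here.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from ._elements import covalent_radius, normalize_symbol

Role = Literal["protein", "ligand"]

#: Tolerance factor applied to the sum of covalent radii when perceiving
#: bonds from geometry alone (used only when no bond records are present).
BOND_TOLERANCE = 1.3


class ParseError(ValueError):
    """A structure file record could not be interpreted."""


@dataclass
class Atom:
    """A typed 3-D point.

    Parameters
    ----------
    serial : int
        Identifier from the source file (or generator).
    element : str
        Canonical element symbol, e.g. ``"C"``, ``"Cl"``.
    coords : ndarray, shape (3,)
        Cartesian coordinates in Angstrom.
    charge : float or None
        Partial charge in elementary-charge units; ``None`` when unknown.
    role : {"protein", "ligand"}
    """

    serial: int
    element: str
    coords: np.ndarray
    charge: float | None = None
    role: Role = "ligand"

    def __post_init__(self) -> None:
        self.element = normalize_symbol(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")


@dataclass
class Molecule:
    """An ordered atom list with an undirected bond list (index pairs)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int]] = []
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                norm.append(key)
        self.bonds = norm

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> list[float | None]:
        return [a.charge for a in self.atoms]

    def with_role(self, role: Role) -> "Molecule":
        """Copy of the molecule with every atom's role set to *role*."""
        return Molecule(
            [replace(a, coords=a.coords.copy(), role=role) for a in self.atoms],
            list(self.bonds),
            self.id,
        )


@dataclass
class ComplexStructure:
    """A protein-ligand pair with disjoint roles; the ligand is never empty."""

    protein: Molecule
    ligand: Molecule

    def __post_init__(self) -> None:
        if len(self.ligand) == 0:
            raise ValueError("complex requires a non-empty ligand")
        self.protein = self.protein.with_role("protein")
        self.ligand = self.ligand.with_role("ligand")

    @property
    def atoms(self) -> list[Atom]:
        """Protein atoms followed by ligand atoms."""
        return list(self.protein.atoms) + list(self.ligand.atoms)


class BondGraph:
    """Covalent connectivity with hop distances D(i, j).

    ``D(i, j)`` is the smallest number of bonds on a path from atom *i* to
    atom *j* (``math.inf`` if unreachable), computed by breadth-first search.
    """

    def __init__(self, n_atoms: int, bonds: Iterable[tuple[int, int]]):
        self.n_atoms = n_atoms
        self.graph = nx.Graph()
        self.graph.add_nodes_from(range(n_atoms))
        self.graph.add_edges_from(bonds)
        self._hops: dict[int, dict[int, int]] = {}

    def hop_distance(self, i: int, j: int) -> float:
        if i == j:
            return 0
        if i not in self._hops:
            self._hops[i] = dict(nx.single_source_shortest_path_length(self.graph, i))
        return self._hops[i].get(j, math.inf)

    def hop_matrix(self) -> np.ndarray:
        """(n, n) matrix of hop distances; ``inf`` marks unreachable pairs."""
        n = self.n_atoms
        out = np.full((n, n), np.inf)
        np.fill_diagonal(out, 0.0)
        for src, lengths in nx.all_pairs_shortest_path_length(self.graph):
            for dst, d in lengths.items():
                out[src, dst] = d
        return out


def build_bond_graph(
    mol: Molecule, mode: Literal["from_records", "distance_cutoff"] = "from_records"
) -> BondGraph:
    """Covalent bond graph either from explicit bond records or from geometry.

    In ``distance_cutoff`` mode two atoms are bonded when their Euclidean
    distance does not exceed ``BOND_TOLERANCE`` times the sum of their
    covalent radii.
    """
    if len(mol) == 0:
        raise ValueError("cannot build a bond graph for an empty molecule")
    if mode == "from_records":
        if not mol.bonds:
            raise ValueError("from_records mode requires a non-empty bond list")
        return BondGraph(len(mol), mol.bonds)
    if mode != "distance_cutoff":
        raise ValueError(f"unknown bond graph mode: {mode!r}")
    coords = mol.coords
    radii = np.array([covalent_radius(e) for e in mol.elements])
    d = cdist(coords, coords)
    thresh = BOND_TOLERANCE * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero((d <= thresh) & (d > 0))
    bonds = [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]
    return BondGraph(len(mol), bonds)


_HEAVY = "heavy"
_ALL = "all"
ElementSet = frozenset[str] | Literal["heavy", "all"] | None


def _label_part(elems: ElementSet) -> str:
    if elems is None:
        return ""
    if isinstance(elems, str):
        return elems
    order = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H"]
    known = [e for e in order if e in elems]
    extra = sorted(e for e in elems if e not in order)
    return "".join(known + extra)


@dataclass(frozen=True)
class ElementSelection:
    """Which (role, element) pairs participate in a persistence computation.

    Each side is a frozenset of symbols, the token ``"heavy"`` (every element
    except hydrogen), the token ``"all"``, or ``None`` (side not selected).
    At least one side must be selected. The complement of the selection is
    the excluded set U used by element-specific correlation filtrations.
    """

    protein_elements: ElementSet = None
    ligand_elements: ElementSet = None

    def __post_init__(self) -> None:
        if self.protein_elements is None and self.ligand_elements is None:
            raise ValueError("selection must name at least one side")
        for side in (self.protein_elements, self.ligand_elements):
            if isinstance(side, str) and side not in (_HEAVY, _ALL):
                raise ValueError(f"unknown selection token {side!r}")

    @classmethod
    def ligand(cls, elements: str | Iterable[str]) -> "ElementSelection":
        return cls(ligand_elements=_parse_elements(elements))

    @classmethod
    def protein(cls, elements: str | Iterable[str]) -> "ElementSelection":
        return cls(protein_elements=_parse_elements(elements))

    @classmethod
    def pair(
        cls, protein: str | Iterable[str], ligand: str | Iterable[str]
    ) -> "ElementSelection":
        return cls(
            protein_elements=_parse_elements(protein),
            ligand_elements=_parse_elements(ligand),
        )

    @property
    def label(self) -> str:
        p, l = _label_part(self.protein_elements), _label_part(self.ligand_elements)
        if p and l:
            return f"{p}-{l}"
        return p or l

    def matches(self, atom: Atom) -> bool:
        side = self.protein_elements if atom.role == "protein" else self.ligand_elements
        if side is None:
            return False
        if side == _ALL:
            return True
        if side == _HEAVY:
            return atom.element != "H"
        return atom.element in side


def _parse_elements(spec: str | Iterable[str]) -> ElementSet:
    """``"CNO"`` or ``"CNOSPFClBrI"`` -> frozenset of symbols; tokens pass through."""
    if isinstance(spec, str):
        if spec in (_HEAVY, _ALL):
            return spec
        out, i = [], 0
        while i < len(spec):
            if i + 1 < len(spec) and spec[i + 1].islower():
                out.append(spec[i : i + 2])
                i += 2
            else:
                out.append(spec[i])
                i += 1
        return frozenset(normalize_symbol(e) for e in out)
    return frozenset(normalize_symbol(e) for e in spec)


def select_atoms(
    struct: Molecule | ComplexStructure, sel: ElementSelection
) -> list[Atom]:
    """Atoms whose (role, element) matches the selection, in input order."""
    atoms = struct.atoms if isinstance(struct, ComplexStructure) else struct.atoms
    return [a for a in atoms if sel.matches(a)]


def truncate_binding_site(cx: ComplexStructure, cutoff: float) -> ComplexStructure:
    """Restrict the protein to atoms within *cutoff* Angstrom of any ligand atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(cx.ligand) == 0:
        raise ValueError("complex has an empty ligand")
    d = cdist(cx.protein.coords, cx.ligand.coords) if len(cx.protein) else np.empty((0, 0))
    keep = sorted(np.nonzero(d.min(axis=1) <= cutoff)[0]) if d.size else []
    index = {old: new for new, old in enumerate(keep)}
    bonds = [
        (index[i], index[j]) for i, j in cx.protein.bonds if i in index and j in index
    ]
    pocket = Molecule([cx.protein.atoms[i] for i in keep], bonds, cx.protein.id)
    return ComplexStructure(pocket, cx.ligand)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_structure(
    path: str | os.PathLike,
    format: Literal["pdb", "mol2"] | None = None,
    role: Role | None = None,
) -> Molecule:
    """Read a PDB or Mol2 file into a :class:`Molecule`.

    The format is inferred from the extension when not given. PDB atoms
    default to the protein role and Mol2 atoms to the ligand role; waters
    (HOH) are skipped and only the first alternate location is kept.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "mol2" if ext == ".mol2" else "pdb"
    if format == "pdb":
        return _read_pdb(path, role or "protein")
    if format == "mol2":
        return _read_mol2(path, role or "ligand")
    raise ValueError(f"unknown format {format!r}")


def _read_pdb(path: str, role: Role) -> Molecule:
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi signals malformed input
        raise ParseError(f"{path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) == 0:
        return Molecule([], id=os.path.basename(path))
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.name in ("HOH", "WAT", "DOD"):
                continue
            seen_names: set[str] = set()
            for at in residue:
                if at.altloc not in ("", "\0", "A"):
                    continue
                if at.name in seen_names:  # duplicate altLoc record
                    continue
                seen_names.add(at.name)
                elem = at.element.name if at.element else at.name[:1]
                atoms.append(
                    Atom(
                        serial=at.serial,
                        element=elem,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        charge=None,
                        role=role,
                    )
                )
    return Molecule(atoms, id=os.path.basename(path))


def _read_mol2(path: str, role: Role) -> Molecule:
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    serial_to_index: dict[int, int] = {}
    mol_id = os.path.basename(path)
    section = None
    mol_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@<TRIPOS>"):
                section = line[len("@<TRIPOS>") :].upper()
                mol_lines = 0
                continue
            if section == "MOLECULE":
                if mol_lines == 0:
                    mol_id = line
                mol_lines += 1
            elif section == "ATOM":
                parts = line.split()
                if len(parts) < 6:
                    raise ParseError(f"{path}:{lineno}: short ATOM record")
                try:
                    serial = int(parts[0])
                    x, y, z = map(float, parts[2:5])
                    elem = parts[5].split(".")[0]
                    charge = float(parts[8]) if len(parts) >= 9 else None
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad ATOM record") from exc
                serial_to_index[serial] = len(atoms)
                atoms.append(
                    Atom(serial, elem, np.array([x, y, z]), charge=charge, role=role)
                )
            elif section == "BOND":
                parts = line.split()
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: short BOND record")
                try:
                    i, j = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad BOND record") from exc
                try:
                    bonds.append((serial_to_index[i], serial_to_index[j]))
                except KeyError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bond references unknown atom id {exc}"
                    ) from exc
    return Molecule(atoms, bonds, id=mol_id)


def write_pdb(mol: Molecule, path: str | os.PathLike) -> None:
    """Write a molecule as a single-chain PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = mol.id or "MOL"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    residue = gemmi.Residue()
    residue.name = "MOL"
    residue.seqid = gemmi.SeqId(1, " ")
    counts: dict[str, int] = {}
    for atom in mol.atoms:
        at = gemmi.Atom()
        counts[atom.element] = counts.get(atom.element, 0) + 1
        at.name = f"{atom.element}{counts[atom.element]}"[:4]
        at.element = gemmi.Element(atom.element)
        at.pos = gemmi.Position(*atom.coords)
        at.serial = atom.serial
        residue.add_atom(at)
    chain.add_residue(residue)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(os.fspath(path))


def write_mol2(mol: Molecule, path: str | os.PathLike) -> None:
    """Write a molecule as a TRIPOS Mol2 file with charges and bonds."""
    lines = [
        "@<TRIPOS>MOLECULE",
        mol.id or "MOL",
        f"{len(mol)} {len(mol.bonds)} 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for k, atom in enumerate(mol.atoms, start=1):
        x, y, z = atom.coords
        q = atom.charge if atom.charge is not None else 0.0
        lines.append(
            f"{k:>7} {atom.element}{k:<4} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
            f"{atom.element:<5} 1 MOL {q:>9.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(mol.bonds, start=1):
        lines.append(f"{k:>6} {i + 1:>5} {j + 1:>5} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
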