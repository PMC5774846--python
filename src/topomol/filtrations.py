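"""Filtration matrices for distance-matrix induced persistent homology.

A :class:`FiltrationMatrix` is a symmetric matrix of filtration values with
an exclusion mask: excluded pairs never form an edge at any filtration
value (the role of the "d-infinity" entries in modified distance matrices).
Variants provided here:

* Euclidean pairwise distances (the plain Rips input),
* multi-level matrices that exclude pairs within ``n`` covalent-bond hops,
  exposing non-covalent contacts in low-dimensional barcodes,
* interactive matrices restricted to cross-group (e.g. protein-ligand)
  pairs,
* correlation-function matrices ``1 - Phi(d; eta, nu)`` on a [0, 1] axis
  (Lorentz kernel by default), optionally element-specific via an excluded
  atom set,
* electrostatic matrices ``Phi = 1 / (1 + exp(-c q_i q_j / d))`` embedding
  partial charges into the filtration axis,
* the per-atom rigidity index and a charge-density scalar-field evaluator.

None of these matrices is assumed to satisfy the triangle inequality; the
Vietoris-Rips construction only needs symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._elements import vdw_radius
from .structures import Atom, BondGraph

#: Default charge-coupling parameter of the electrostatic filtration.
DEFAULT_C = 100.0


def _coords_of(atoms: Sequence[Atom] | np.ndarray) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return np.asarray(atoms, dtype=float).reshape(-1, 3)
    return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class FiltrationMatrix:
    """Symmetric filtration values with an excluded-pair mask.

    Attributes
    ----------
    values : ndarray (n, n)
        Filtration values; the diagonal is zero. Entries of excluded pairs
        are irrelevant (kept at 0).
    excluded : ndarray (n, n) of bool
        Pairs that never form simplices at any filtration value.
    scheme : str
        Provenance tag, e.g. ``"euclidean"``, ``"multilevel(1)"``,
        ``"interactive"``, ``"correlation(lorentz)"``, ``"electrostatic(100)"``.
    axis_range : (float, float)
        Closed interval of admissible filtration values.
    """

    values: np.ndarray
    excluded: np.ndarray = None  # type: ignore[assignment]
    scheme: str = "euclidean"
    axis_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("filtration values must be a square matrix")
        if not np.allclose(v, v.T):
            raise ValueError("filtration values must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("filtration diagonal must be zero")
        self.values = v
        if self.excluded is None:
            self.excluded = np.zeros_like(v, dtype=bool)
        else:
            e = np.asarray(self.excluded, dtype=bool)
            if e.shape != v.shape or not np.array_equal(e, e.T):
                raise ValueError("exclusion mask must be square and symmetric")
            self.excluded = e
        if self.axis_range is None:
            finite = self.finite_values
            hi = float(finite.max()) if finite.size else 0.0
            self.axis_range = (0.0, hi)
        off = ~np.eye(len(v), dtype=bool) & ~self.excluded
        if off.any() and (v[off] < 0).any():
            raise ValueError("filtration values must be non-negative")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def finite_values(self) -> np.ndarray:
        """Off-diagonal values of non-excluded pairs (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        keep = ~self.excluded[iu]
        return self.values[iu][keep]

    def finite_edges(self) -> list[tuple[float, int, int]]:
        """Sorted ``(value, i, j)`` triples over non-excluded pairs, i < j."""
        ii, jj = np.triu_indices(self.n, k=1)
        keep = ~self.excluded[ii, jj]
        out = [
            (float(v), int(i), int(j))
            for v, i, j in zip(self.values[ii, jj][keep], ii[keep], jj[keep])
        ]
        out.sort()
        return out

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str) -> None:
        """Dense TSV with an ``INF`` sentinel for excluded pairs."""
        with open(path, "w") as fh:
            fh.write(
                f"#scheme={self.scheme}\taxis={self.axis_range[0]:g},{self.axis_range[1]:g}\n"
            )
            for i in range(self.n):
                row = [
                    "INF" if self.excluded[i, j] and i != j else f"{self.values[i, j]:.10g}"
                    for j in range(self.n)
                ]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "FiltrationMatrix":
        scheme, axis = "euclidean", None
        rows: list[list[str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split("\t"):
                        key, _, val = tok.partition("=")
                        if key == "scheme":
                            scheme = val
                        elif key == "axis":
                            lo, hi = val.split(",")
                            axis = (float(lo), float(hi))
                    continue
                if line:
                    rows.append(line.split("\t"))
        n = len(rows)
        values = np.zeros((n, n))
        excluded = np.zeros((n, n), dtype=bool)
        for i, row in enumerate(rows):
            for j, tok in enumerate(row):
                if tok == "INF":
                    excluded[i, j] = True
                else:
                    values[i, j] = float(tok)
        return cls(values, excluded, scheme, axis)


@dataclass(frozen=True)
class KernelSpec:
    """Radial kernel used by correlation and electrostatic filtrations.

    ``eta`` is the scale in Angstrom; when ``None`` the per-pair scale
    defaults to the sum of the two atoms' van der Waals radii. ``nu`` is
    the Lorentz power, ``c`` the signed electrostatic coupling.
    """

    family: str = "lorentz"
    eta: float | None = None
    nu: float = 2.0
    c: float = DEFAULT_C

    def __post_init__(self) -> None:
        if self.family not in ("lorentz", "exponential", "electrostatic_sigmoid"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.family == "electrostatic_sigmoid" and self.c == 0:
            raise ValueError("electrostatic kernel requires c != 0")

    def phi(self, d: np.ndarray, eta: np.ndarray | float) -> np.ndarray:
        """Evaluate Phi(d; eta) for the lorentz / exponential families."""
        d = np.asarray(d, dtype=float)
        if self.family == "lorentz":
            return 1.0 / (1.0 + (d / eta) ** self.nu)
        if self.family == "exponential":
            return np.exp(-((d / eta) ** self.nu))
        raise ValueError("phi(d, eta) undefined for the electrostatic kernel")


def _pair_eta(atoms: Sequence[Atom], kernel: KernelSpec) -> np.ndarray:
    if kernel.eta is not None:
        n = len(atoms)
        return np.full((n, n), float(kernel.eta))
    r = np.array([vdw_radius(a.element) for a in atoms])
    return r[:, None] + r[None, :]


def euclidean_matrix(atoms: Sequence[Atom] | np.ndarray) -> FiltrationMatrix:
    """Pairwise Euclidean distances in Angstrom; nothing excluded."""
    coords = _coords_of(atoms)
    if coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    d = cdist(coords, coords)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return FiltrationMatrix(d, scheme="euclidean")


def multilevel_matrix(
    atoms: Sequence[Atom] | np.ndarray, graph: BondGraph, level: int = 1
) -> FiltrationMatrix:
    """Euclidean distances with pairs within *level* bond hops excluded.

    Level-1 removes covalently bonded pairs, so the 0th-dimensional barcode
    reports non-covalent contact distances and higher-dimensional barcodes
    are substantially enriched for small molecules.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    base = euclidean_matrix(atoms)
    if graph.n_atoms != base.n:
        raise ValueError("bond graph does not cover the atom set")
    hops = graph.hop_matrix()
    excluded = hops <= level
    np.fill_diagonal(excluded, False)
    return FiltrationMatrix(
        base.values,
        excluded,
        scheme=f"multilevel({level})",
        axis_range=base.axis_range,
    )


def interactive_matrix(
    atoms: Sequence[Atom],
    base: FiltrationMatrix | None = None,
    partition: tuple[Sequence[int], Sequence[int]] | None = None,
) -> FiltrationMatrix:
    """Keep only cross-partition pairs; within-group pairs are excluded.

    The partition defaults to the atoms' protein/ligand roles. ``base``
    defaults to the Euclidean matrix; passing an electrostatic matrix gives
    the charged interactive filtration.
    """
    if partition is None:
        a1 = [k for k, a in enumerate(atoms) if a.role == "protein"]
        a2 = [k for k, a in enumerate(atoms) if a.role == "ligand"]
    else:
        a1, a2 = [list(p) for p in partition]
    if not a1 or not a2:
        raise ValueError("both partition groups must be non-empty")
    if set(a1) & set(a2):
        raise ValueError("partition groups must be disjoint")
    if base is None:
        base = euclidean_matrix(atoms)
    n = base.n
    if n != len(atoms):
        raise ValueError("base matrix does not match the atom set")
    cross = np.zeros((n, n), dtype=bool)
    cross[np.ix_(a1, a2)] = True
    cross[np.ix_(a2, a1)] = True
    excluded = ~cross | base.excluded
    np.fill_diagonal(excluded, False)
    return FiltrationMatrix(
        base.values, excluded, scheme=f"interactive[{base.scheme}]", axis_range=base.axis_range
    )


def correlation_matrix(
    atoms: Sequence[Atom],
    kernel: KernelSpec | None = None,
    excluded_set: Iterable[int] = (),
) -> FiltrationMatrix:
    """Correlation-function filtration ``1 - Phi(d_ij; eta_ij)`` on [0, 1].

    ``excluded_set`` holds atom indices (the set U of the element-specific
    variant); every pair touching U is excluded.
    """
    kernel = kernel or KernelSpec()
    coords = _coords_of(atoms)
    d = cdist(coords, coords)
    eta = _pair_eta(atoms, kernel)
    values = 1.0 - kernel.phi(d, eta)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 0.0)
    excluded = np.zeros_like(values, dtype=bool)
    u = list(excluded_set)
    if u:
        excluded[u, :] = True
        excluded[:, u] = True
        np.fill_diagonal(excluded, False)
    return FiltrationMatrix(
        values, excluded, scheme=f"correlation({kernel.family})", axis_range=(0.0, 1.0)
    )


def electrostatic_value(d: float, qi: float, qj: float, c: float = DEFAULT_C) -> float:
    """Sigmoid charge correlation ``1 / (1 + exp(-c q_i q_j / d))``.

    With ``c > 0`` attractive (opposite-sign) pairs map into (0, 0.5),
    repulsive pairs into (0.5, 1), and weak interactions approach 0.5.
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    if c == 0:
        raise ValueError("c must be nonzero")
    x = c * qi * qj / d
    # exp overflow-safe evaluation of the logistic function
    if x >= 0:
        return float(1.0 / (1.0 + math.exp(-x))) if x < 700 else 1.0
    return float(math.exp(x) / (1.0 + math.exp(x))) if x > -700 else 0.0


def electrostatic_matrix(
    atoms: Sequence[Atom], c: float = DEFAULT_C
) -> FiltrationMatrix:
    """Pairwise electrostatic correlation values as a [0, 1] filtration."""
    for k, a in enumerate(atoms):
        if a.charge is None:
            raise ValueError(f"atom index {k} (serial {a.serial}) has no partial charge")
    coords = _coords_of(atoms)
    q = np.array([a.charge for a in atoms], dtype=float)
    d = cdist(coords, coords)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(d > 0, c * np.outer(q, q) / np.where(d > 0, d, 1.0), 0.0)
    values = 1.0 / (1.0 + np.exp(np.clip(-x, -700, 700)))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return FiltrationMatrix(
        values, scheme=f"electrostatic({c:g})", axis_range=(0.0, 1.0)
    )


def rigidity_index(
    atoms: Sequence[Atom], kernel: KernelSpec | None = None
) -> np.ndarray:
    """Per-atom rigidity index ``mu_i = sum_{j != i} Phi(d_ij; eta_ij, nu)``."""
    kernel = kernel or KernelSpec()
    if kernel.family != "lorentz":
        raise ValueError("rigidity index is defined for the lorentz kernel")
    coords = _coords_of(atoms)
    n = coords.shape[0]
    if n == 1:
        return np.zeros(1)
    d = cdist(coords, coords)
    eta = _pair_eta(atoms, kernel)
    phi = kernel.phi(d, eta)
    np.fill_diagonal(phi, 0.0)
    return phi.sum(axis=1)


def charge_density(
    atoms: Sequence[Atom],
    r: np.ndarray,
    eta: float | Sequence[float] | None = None,
) -> float:
    """Charge density ``mu_c(r) = sum_j q_j exp(-|r - r_j| / eta_j)``.

    Provided as a scalar-field evaluator (no cubical filtration is built
    on top of it).
    """
    r = np.asarray(r, dtype=float).reshape(3)
    coords = _coords_of(atoms)
    q = np.array(
        [a.charge if a.charge is not None else 0.0 for a in atoms], dtype=float
    )
    if any(a.charge is None for a in atoms):
        raise ValueError("all atoms must carry partial charges")
    if eta is None:
        etas = np.array([vdw_radius(a.element) for a in atoms])
    else:
        etas = np.broadcast_to(np.asarray(eta, dtype=float), (len(atoms),))
    dist = np.linalg.norm(coords - r[None, :], axis=1)
    return float(np.sum(q * np.exp(-dist / etas)))
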