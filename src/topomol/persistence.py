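"""Persistent homology of filtration matrices and point clouds.

Two constructions are supported:

* **Vietoris-Rips** on an arbitrary symmetric :class:`~topomol.filtrations.FiltrationMatrix`
  (metric axioms are not required): a simplex enters the filtration when
  all its pairwise values are within the scale parameter; excluded pairs
  never form edges.
* **Alpha** on explicit coordinates: simplices of the Delaunay
  triangulation enter at radius ``r`` once every edge has length at most
  ``2r`` (so an edge of length ``L`` enters at ``r = L/2``).

Homology is computed over the Z2 field by column reduction of the boundary
matrix in filtration order. The production path packs columns into Python
integers (bitmasks) for fast XOR; two deliberately naive oracles —
Kruskal/union-find for dimension 0 and a dense Z2 Gaussian elimination for
all dimensions — are provided for independent verification and are kept as
separate code paths.

Bars of zero persistence are dropped; classes alive at the filtration cap
are reported as OPEN (death = +inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import cdist, pdist, squareform

from .filtrations import FiltrationMatrix

OPEN = math.inf

#: Default filtration caps, by feature context (Angstrom, except the
#: dimensionless electrostatic axis).
DEFAULT_CAPS = {
    "complex": 12.0,
    "interactive": 50.0,
    "electrostatic": 1.0,
    "ligand_alpha": 5.0,
}


@dataclass(frozen=True)
class Bar:
    """A persistence interval [birth, death) in homology dimension ``dim``."""

    dim: int
    birth: float
    death: float  # OPEN (= +inf) for classes alive at the cap

    def __post_init__(self) -> None:
        if self.dim < 0:
            raise ValueError("dimension must be non-negative")
        if self.death < self.birth:
            raise ValueError("death must not precede birth")

    @property
    def is_open(self) -> bool:
        return math.isinf(self.death)

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    def capped(self, cap: float) -> "Bar":
        """Close an OPEN bar at *cap* (identity for closed bars)."""
        if self.is_open:
            return Bar(self.dim, self.birth, cap)
        return self


@dataclass
class Barcode:
    """A multiset of bars plus the filtration context that produced it."""

    bars: list[Bar]
    cap: float
    complex: str = "rips"  # {"rips", "alpha"}
    provenance: tuple = ()

    def of_dim(self, dim: int) -> list[Bar]:
        return [b for b in self.bars if b.dim == dim]

    def __len__(self) -> int:
        return len(self.bars)

    def capped(self) -> "Barcode":
        """Barcode with every OPEN bar closed at the cap."""
        return Barcode(
            [b.capped(self.cap) for b in self.bars], self.cap, self.complex, self.provenance
        )

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#{self.complex}\t{' '.join(map(str, self.provenance))}\t{self.cap:g}\n")
            for b in sorted(self.bars, key=lambda b: (b.dim, b.birth, b.death)):
                death = "inf" if b.is_open else f"{b.death:.10g}"
                fh.write(f"{b.dim}\t{b.birth:.10g}\t{death}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "Barcode":
        bars: list[Bar] = []
        complex_, cap, prov = "rips", math.inf, ()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split("\t")
                    complex_ = parts[0]
                    if len(parts) >= 3:
                        prov = tuple(parts[1].split())
                        cap = float(parts[2])
                    continue
                dim, birth, death = line.split("\t")
                bars.append(Bar(int(dim), float(birth), float(death)))
        return cls(bars, cap, complex_, prov)


# ---------------------------------------------------------------------------
# Filtered complex construction
# ---------------------------------------------------------------------------


def rips_complex(
    m: FiltrationMatrix, max_dim: int, cap: float
) -> list[tuple[float, tuple[int, ...]]]:
    """Filtered Vietoris-Rips complex as sorted ``(value, simplex)`` pairs.

    Simplices up to dimension ``max_dim + 1`` are generated (the cofaces
    needed to kill ``max_dim``-dimensional classes). A simplex's value is
    the largest pairwise value among its vertices; simplices containing an
    excluded or beyond-cap pair are omitted.
    """
    n = m.n
    vals = m.values
    simplices: list[tuple[float, tuple[int, ...]]] = [(0.0, (i,)) for i in range(n)]
    edge_ok = (~m.excluded) & (vals <= cap)
    np.fill_diagonal(edge_ok, False)
    adj: list[set[int]] = [set(np.nonzero(edge_ok[i])[0].tolist()) for i in range(n)]
    edges = [
        (float(vals[i, j]), (i, j)) for i in range(n) for j in adj[i] if j > i
    ]
    simplices.extend(edges)

    def expand(simplex: tuple[int, ...], value: float, candidates: set[int], depth: int):
        if depth == 0:
            return
        for v in sorted(candidates):
            new_val = max(value, max(float(vals[u, v]) for u in simplex))
            new_simplex = simplex + (v,)
            simplices.append((new_val, new_simplex))
            expand(new_simplex, new_val, candidates & adj[v] & _above(v), depth - 1)

    def _above(v: int) -> set[int]:
        return {u for u in range(v + 1, n)}

    if max_dim + 1 >= 2:
        for value, (i, j) in edges:
            cands = adj[i] & adj[j] & {u for u in range(j + 1, n)}
            expand((i, j), value, cands, max_dim + 1 - 1)
    simplices.sort(key=lambda s: (s[0], len(s[1]), s[1]))
    return simplices


def alpha_complex(
    coords: np.ndarray, max_dim: int = 2
) -> list[tuple[float, tuple[int, ...]]]:
    """Filtered Delaunay complex under the half-longest-edge entry rule.

    Each Delaunay simplex (and each of its faces) enters at ``r`` equal to
    half its longest edge. For four or fewer points, or degenerate inputs
    Qhull rejects, the complete simplicial complex is used instead (it
    coincides with the Delaunay complex for points in general position at
    these sizes).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] not in (2, 3):
        raise ValueError("coords must be an (n, 2) or (n, 3) array")
    n = coords.shape[0]
    if n == 0:
        raise ValueError("need at least one point")
    if n > 1 and np.allclose(pdist(coords), 0.0):
        raise ValueError("all points coincide; alpha filtration undefined")
    d = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))

    top_cells: list[tuple[int, ...]]
    if n <= coords.shape[1] + 1:
        top_cells = [tuple(range(n))]
    else:
        try:
            tri = Delaunay(coords)
            top_cells = [tuple(sorted(s)) for s in tri.simplices]
        except QhullError:
            if n <= 8:
                top_cells = [tuple(range(n))]
            else:
                raise
    faces: set[tuple[int, ...]] = set()
    for cell in top_cells:
        for k in range(1, len(cell) + 1):
            faces.update(combinations(cell, k))
    simplices = []
    for f in faces:
        if len(f) == 1:
            simplices.append((0.0, f))
        elif len(f) <= max_dim + 2:
            value = max(float(d[i, j]) for i, j in combinations(f, 2)) / 2.0
            simplices.append((value, f))
    simplices.sort(key=lambda s: (s[0], len(s[1]), s[1]))
    return simplices


# ---------------------------------------------------------------------------
# Boundary-matrix reduction (production path: bitmask columns)
# ---------------------------------------------------------------------------


def _reduce_filtration(
    simplices: list[tuple[float, tuple[int, ...]]], max_dim: int
) -> list[Bar]:
    """Z2 persistence pairs of a sorted filtered complex via bitmask reduction."""
    index_of = {s: k for k, (_, s) in enumerate(simplices)}
    nsimp = len(simplices)
    low_inv: dict[int, int] = {}  # lowest one -> column index holding it
    columns: dict[int, int] = {}  # column index -> reduced bitmask
    positive: list[bool] = [False] * nsimp
    bars: list[Bar] = []
    for j, (value, simplex) in enumerate(simplices):
        k = len(simplex) - 1
        if k == 0:
            positive[j] = True
            continue
        col = 0
        for face in combinations(simplex, k):
            col ^= 1 << index_of[face]
        while col:
            low = col.bit_length() - 1
            holder = low_inv.get(low)
            if holder is None:
                break
            col ^= columns[holder]
        if col == 0:
            positive[j] = True
            continue
        low = col.bit_length() - 1
        low_inv[low] = j
        columns[j] = col
        positive[low] = False
        birth_val, birth_simplex = simplices[low]
        if value > birth_val and len(birth_simplex) - 1 <= max_dim:
            bars.append(Bar(len(birth_simplex) - 1, birth_val, value))
    for j, (value, simplex) in enumerate(simplices):
        k = len(simplex) - 1
        if positive[j] and k <= max_dim:
            bars.append(Bar(k, value, OPEN))
    bars.sort(key=lambda b: (b.dim, b.birth, b.death))
    return bars


def rips_persistence(
    m: FiltrationMatrix,
    max_dim: int = 2,
    cap: float | None = None,
    provenance: tuple = (),
) -> Barcode:
    """Barcode of the Vietoris-Rips filtration of a filtration matrix."""
    if max_dim > 2:
        raise ValueError("dimensions above 2 are not supported")
    if cap is None:
        cap = m.axis_range[1]
    elif not (m.axis_range[0] <= cap):
        raise ValueError("cap below the filtration axis range")
    simplices = rips_complex(m, max_dim, cap)
    bars = _reduce_filtration(simplices, max_dim)
    return Barcode(bars, cap, "rips", provenance or (m.scheme,))


def alpha_persistence(
    coords: np.ndarray, max_dim: int = 2, provenance: tuple = ()
) -> Barcode:
    """Barcode of the alpha (Delaunay, half-edge rule) filtration."""
    if max_dim > 2:
        raise ValueError("dimensions above 2 are not supported")
    simplices = alpha_complex(coords, max_dim)
    bars = _reduce_filtration(simplices, max_dim)
    cap = max(v for v, _ in simplices) if simplices else 0.0
    return Barcode(bars, cap, "alpha", provenance)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def persistence_oracle_0d(m: FiltrationMatrix, cap: float | None = None) -> Barcode:
    """Dimension-0 barcode by Kruskal/union-find (single linkage).

    Deliberately independent of the boundary-reduction path: merge events
    of the minimum spanning forest over finite edges are the deaths; each
    surviving component yields one OPEN bar.
    """
    if cap is None:
        cap = m.axis_range[1]
    parent = list(range(m.n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bars: list[Bar] = []
    for value, i, j in m.finite_edges():
        if value > cap:
            break
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            if value > 0:
                bars.append(Bar(0, 0.0, value))
    n_components = sum(1 for k in range(m.n) if find(k) == k)
    bars.extend(Bar(0, 0.0, OPEN) for _ in range(n_components))
    bars.sort(key=lambda b: (b.dim, b.birth, b.death))
    return Barcode(bars, cap, "rips", (m.scheme, "oracle-0d"))


def persistence_oracle_reduction(
    simplices: Sequence[tuple[float, tuple[int, ...]]]
) -> Barcode:
    """All-dimension barcode by dense Z2 Gaussian elimination.

    Takes an explicit filtered complex (``(value, vertex-tuple)`` pairs),
    checks closure under faces and filtration monotonicity, and reduces the
    full dense boundary matrix with numpy boolean arithmetic. Intended for
    complexes of at most a few hundred simplices.
    """
    simplices = sorted(simplices, key=lambda s: (s[0], len(s[1]), tuple(sorted(s[1]))))
    simplices = [(float(v), tuple(sorted(s))) for v, s in simplices]
    value_of = {}
    for v, s in simplices:
        value_of[s] = min(v, value_of.get(s, math.inf))
    for v, s in simplices:
        if len(s) > 1:
            for face in combinations(s, len(s) - 1):
                if face not in value_of:
                    raise ValueError(f"complex not closed under faces: missing {face}")
                if value_of[face] > v:
                    raise ValueError("filtration not monotone on faces")
    nsimp = len(simplices)
    index_of = {s: k for k, (_, s) in enumerate(simplices)}
    boundary = np.zeros((nsimp, nsimp), dtype=bool)
    for j, (_, s) in enumerate(simplices):
        if len(s) > 1:
            for face in combinations(s, len(s) - 1):
                boundary[index_of[face], j] = True
    lows = np.full(nsimp, -1)
    for j in range(nsimp):
        col = boundary[:, j]
        while col.any():
            low = int(np.nonzero(col)[0].max())
            prior = np.nonzero(lows[:j] == low)[0]
            if prior.size == 0:
                break
            col ^= boundary[:, int(prior[0])]
        boundary[:, j] = col
        lows[j] = int(np.nonzero(col)[0].max()) if col.any() else -1
    bars: list[Bar] = []
    paired = set()
    for j in range(nsimp):
        if lows[j] >= 0:
            i = int(lows[j])
            paired.update((i, j))
            birth, bs = simplices[i]
            death, _ = simplices[j]
            if death > birth:
                bars.append(Bar(len(bs) - 1, birth, death))
    for j in range(nsimp):
        if lows[j] < 0 and j not in paired:
            value, s = simplices[j]
            bars.append(Bar(len(s) - 1, value, OPEN))
    bars.sort(key=lambda b: (b.dim, b.birth, b.death))
    cap = max((v for v, _ in simplices), default=0.0)
    return Barcode(bars, cap, "explicit", ("oracle-reduction",))
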