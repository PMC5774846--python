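"""Bottleneck and Wasserstein distances between barcodes.

A matching between two barcodes pairs some bars of one with some bars of
the other; matched pairs are penalized by the l-infinity gap
``Delta(I1, I2) = max(|b2 - b1|, |d2 - d1|)`` and unmatched bars by half
their persistence ``lambda(I) = (d - b) / 2`` (the cost of collapsing the
bar to the diagonal). The bottleneck distance minimizes the maximum
penalty over matchings; the p-Wasserstein distance minimizes the p-power
sum and takes the 1/p root. Distances are computed exactly via the
standard augmented bipartite construction (every bar may match a diagonal
copy) with an optimal assignment solver; a brute-force enumeration over
all partial bijections serves as an independent oracle for small inputs.

OPEN bars are closed at the barcode cap before any metric computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .filtrations import euclidean_matrix, multilevel_matrix
from .persistence import DEFAULT_CAPS, Bar, Barcode, rips_persistence
from .structures import ElementSelection, Molecule, build_bond_graph, select_atoms
from .vectorize import KNN_COMBINATIONS, _SubsetBondGraph


def bar_gap(i1: Bar, i2: Bar) -> float:
    """l-infinity distance between two closed bars."""
    if i1.is_open or i2.is_open:
        raise ValueError("metrics operate on capped bars; close OPEN bars first")
    return max(abs(i2.birth - i1.birth), abs(i2.death - i1.death))


def bar_diag(i: Bar) -> float:
    """Half-persistence: the cost of leaving a bar unmatched."""
    if i.is_open:
        raise ValueError("metrics operate on capped bars; close OPEN bars first")
    return (i.death - i.birth) / 2.0


@dataclass(frozen=True)
class Matching:
    """A partial bijection between two bar index sets."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        left = [i for i, _ in self.pairs]
        right = [j for _, j in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("matching must be injective on both sides")


def _as_bars(b, dim: int | None) -> list[Bar]:
    if isinstance(b, Barcode):
        bars = b.capped().bars
        if dim is not None:
            bars = [bar for bar in bars if bar.dim == dim]
        return bars
    return list(b)


def matching_penalty(
    b1: Sequence[Bar] | Barcode,
    b2: Sequence[Bar] | Barcode,
    theta: Matching,
    p: float = 2.0,
    dim: int | None = None,
) -> float:
    """Penalty of a given matching: p-power sum, or the max form for p=inf."""
    bars1, bars2 = _as_bars(b1, dim), _as_bars(b2, dim)
    matched1 = {i for i, _ in theta.pairs}
    matched2 = {j for _, j in theta.pairs}
    gaps = [bar_gap(bars1[i], bars2[j]) for i, j in theta.pairs]
    lambdas = [bar_diag(bars1[i]) for i in range(len(bars1)) if i not in matched1]
    lambdas += [bar_diag(bars2[j]) for j in range(len(bars2)) if j not in matched2]
    if math.isinf(p):
        return max(gaps + lambdas, default=0.0)
    return sum(g**p for g in gaps) + sum(l**p for l in lambdas)


def wasserstein_distance(
    b1: Sequence[Bar] | Barcode,
    b2: Sequence[Bar] | Barcode,
    p: float = 2.0,
    dim: int | None = None,
) -> float:
    """Exact p-Wasserstein barcode distance (default p = 2)."""
    bars1, bars2 = _as_bars(b1, dim), _as_bars(b2, dim)
    n, m = len(bars1), len(bars2)
    if n == 0 and m == 0:
        return 0.0
    cost = np.zeros((n + m, m + n))
    for i, a in enumerate(bars1):
        la = bar_diag(a) ** p
        for j, b in enumerate(bars2):
            cost[i, j] = bar_gap(a, b) ** p
        cost[i, m:] = la
    for j, b in enumerate(bars2):
        cost[n:, j] = bar_diag(b) ** p
    # diagonal-to-diagonal entries stay zero
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() ** (1.0 / p))


def bottleneck_distance(
    b1: Sequence[Bar] | Barcode,
    b2: Sequence[Bar] | Barcode,
    dim: int | None = None,
) -> float:
    """Exact bottleneck distance via threshold search over candidate costs."""
    bars1, bars2 = _as_bars(b1, dim), _as_bars(b2, dim)
    n, m = len(bars1), len(bars2)
    if n == 0 and m == 0:
        return 0.0
    gap = np.array([[bar_gap(a, b) for b in bars2] for a in bars1]).reshape(n, m)
    lam1 = np.array([bar_diag(a) for a in bars1])
    lam2 = np.array([bar_diag(b) for b in bars2])
    candidates = np.unique(np.concatenate([gap.ravel(), lam1, lam2, [0.0]]))

    def feasible(t: float) -> bool:
        # bipartite graph: bars1 + diag copies vs bars2 + diag copies
        rows, cols = [], []
        for i in range(n):
            for j in range(m):
                if gap[i, j] <= t:
                    rows.append(i)
                    cols.append(j)
            if lam1[i] <= t:
                for k in range(n):
                    rows.append(i)
                    cols.append(m + k)
        for j in range(m):
            if lam2[j] <= t:
                for k in range(m):
                    rows.append(n + k)
                    cols.append(j)
        for k in range(m):
            for k2 in range(n):
                rows.append(n + k)
                cols.append(m + k2)
        graph = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n + m, m + n)
        )
        match = maximum_bipartite_matching(graph, perm_type="column")
        return bool((match >= 0).all())

    lo, hi = 0, len(candidates) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if feasible(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def matching_oracle(
    bars1: Sequence[Bar], bars2: Sequence[Bar], p: float = 2.0
) -> float:
    """Brute-force minimum over all partial bijections (small inputs only).

    Returns the distance (1/p root of the minimal penalty for finite p,
    the minimal max-penalty for p = inf).
    """
    n, m = len(bars1), len(bars2)
    best = math.inf
    for k in range(min(n, m) + 1):
        for left in combinations(range(n), k):
            for right in combinations(range(m), k):
                for perm in permutations(right):
                    theta = Matching(tuple(zip(left, perm)))
                    pen = matching_penalty(bars1, bars2, theta, p)
                    best = min(best, pen)
    if math.isinf(p):
        return best
    return best ** (1.0 / p)


# ---------------------------------------------------------------------------
# Molecule-level similarity
# ---------------------------------------------------------------------------

#: The six barcode sets of the default ligand similarity: homology
#: dimensions 0-2 under the Euclidean and the level-1 multi-level matrices.
DEFAULT_SIMILARITY_SPEC = tuple(
    (scheme, dim) for scheme in ("euclidean", "multilevel") for dim in (0, 1, 2)
)


def ligand_barcode_set(
    mol: Molecule,
    combinations: Sequence[str] = KNN_COMBINATIONS,
    schemes: Sequence[str] = ("euclidean", "multilevel"),
    cap: float = DEFAULT_CAPS["complex"],
    level: int = 1,
) -> dict[tuple[str, str], Barcode]:
    """Barcodes of a ligand per (element combination, scheme), dims 0-2."""
    out: dict[tuple[str, str], Barcode] = {}
    hop = None
    if "multilevel" in schemes:
        graph = build_bond_graph(
            mol, "from_records" if mol.bonds else "distance_cutoff"
        )
        hop = graph.hop_matrix()
    for combo in combinations:
        sel = ElementSelection.ligand(combo)
        idx = [k for k, a in enumerate(mol.atoms) if sel.matches(a)]
        atoms = [mol.atoms[k] for k in idx]
        for scheme in schemes:
            key = (combo, scheme)
            if not atoms:
                out[key] = Barcode([], cap, "rips", (mol.id, combo, scheme))
                continue
            if scheme == "euclidean":
                matrix = euclidean_matrix(atoms)
            elif scheme == "multilevel":
                matrix = multilevel_matrix(
                    atoms, _SubsetBondGraph(hop[np.ix_(idx, idx)]), level=level
                )
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            out[key] = rips_persistence(
                matrix, max_dim=2, cap=cap, provenance=(mol.id, combo, scheme)
            )
    return out


def molecule_similarity(
    m1: Molecule,
    m2: Molecule,
    spec: Sequence[tuple[str, int]] = DEFAULT_SIMILARITY_SPEC,
    combinations: Sequence[str] = KNN_COMBINATIONS,
    p: float = 2.0,
) -> float:
    """Mean Wasserstein distance over (combination x scheme x dimension).

    Zero for identical molecules; invariant under rigid motions for the
    Euclidean scheme.
    """
    if not spec:
        raise ValueError("similarity spec must be non-empty")
    schemes = sorted({scheme for scheme, _ in spec})
    set1 = ligand_barcode_set(m1, combinations, schemes)
    set2 = ligand_barcode_set(m2, combinations, schemes)
    dists = []
    for combo in combinations:
        for scheme, dim in spec:
            d = wasserstein_distance(
                set1[(combo, scheme)], set2[(combo, scheme)], p=p, dim=dim
            )
            dists.append(d)
    return float(np.mean(dists))


def pairwise_similarity_matrix(
    mols: Sequence[Molecule],
    spec: Sequence[tuple[str, int]] = DEFAULT_SIMILARITY_SPEC,
    combinations: Sequence[str] = KNN_COMBINATIONS,
    p: float = 2.0,
) -> np.ndarray:
    """Symmetric matrix of pairwise molecule similarities (distances)."""
    schemes = sorted({scheme for scheme, _ in spec})
    sets = [ligand_barcode_set(m, combinations, schemes) for m in mols]
    n = len(mols)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dists = [
                wasserstein_distance(sets[i][(c, s)], sets[j][(c, s)], p=p, dim=d)
                for c in combinations
                for s, d in spec
            ]
            out[i, j] = out[j, i] = float(np.mean(dists))
    return out


def export_distance_matrix(
    mols: Sequence[Molecule], matrix: np.ndarray, path: str
) -> None:
    """Square headered CSV keyed by molecule id."""
    ids = [m.id or f"mol{k}" for k, m in enumerate(mols)]
    with open(path, "w") as fh:
        fh.write("id," + ",".join(ids) + "\n")
        for i, row in enumerate(matrix):
            fh.write(ids[i] + "," + ",".join(f"{v:.10g}" for v in row) + "\n")
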