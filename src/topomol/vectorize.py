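"""Barcode vectorization and named feature groups.

Three vectorizers turn barcodes into fixed-length numeric features:

* **counts in bins** — numbers of births, deaths, and bin-overlapping
  persistence intervals per bin (dimension-0 features use death counts
  only, since every dim-0 bar is born at zero);
* **barcode statistics** — avg/std/max/min/sum/count of the birth, death
  and persistence sets, with the longest bar's endpoints appended to the
  persistence block;
* **persistence-diagram slice statistics** — the diagram is sliced along
  the birth, death or persistence axis and each slice is summarized by the
  statistics of the complementary coordinate(s).

Feature *groups* are registered recipes naming the complex type, the
filtration scheme, the homology dimensions, the element-combination list
and the vectorizer; the registry reproduces the standard configurations
used for ligand characterization and protein-ligand complex scoring
(including the 32/36-combination ligand lists, the 160/36-pair interactive
lists, the 50-pair electrostatic list and the 128-combination image list).
Multi-channel 2-D topological images stack per-combination count vectors
into a (bins x combinations x channels) tensor with eight channels per
structure and sixteen for a complex (complex plus complex-minus-protein
differences).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .filtrations import (
    DEFAULT_C,
    electrostatic_matrix,
    euclidean_matrix,
    interactive_matrix,
    multilevel_matrix,
)
from .persistence import (
    DEFAULT_CAPS,
    Bar,
    Barcode,
    alpha_persistence,
    rips_persistence,
)
from .structures import (
    ComplexStructure,
    ElementSelection,
    Molecule,
    build_bond_graph,
    select_atoms,
)

# ---------------------------------------------------------------------------
# Bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinSpec:
    """Ordered bins on the filtration axis with per-bin closure conventions."""

    intervals: tuple[tuple[float, float], ...]
    closures: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.closures):
            raise ValueError("one closure per interval required")
        prev_r = -math.inf
        for (l, r), cl in zip(self.intervals, self.closures):
            if r < l:
                raise ValueError(f"bin ({l}, {r}) reversed")
            if l < prev_r:
                raise ValueError("bins overlap")
            if cl not in ("[]", "[)", "(]", "()"):
                raise ValueError(f"unknown closure {cl!r}")
            prev_r = r

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[tuple[float, float]], closure: str = "[)", last: str = "[]"
    ) -> "BinSpec":
        closures = [closure] * len(intervals)
        if closures:
            closures[-1] = last
        return cls(tuple((float(l), float(r)) for l, r in intervals), tuple(closures))

    @classmethod
    def uniform(
        cls, lo: float, hi: float, n: int, closure: str = "[)", last: str = "[]"
    ) -> "BinSpec":
        edges = np.linspace(lo, hi, n + 1)
        return cls.from_intervals(list(zip(edges[:-1], edges[1:])), closure, last)

    def contains(self, i: int, x: float) -> bool:
        (l, r), cl = self.intervals[i], self.closures[i]
        left = x >= l if cl[0] == "[" else x > l
        right = x <= r if cl[1] == "]" else x < r
        return left and right


#: Bins of the interactive-distance dim-0 count features (Angstrom).
INTERACTIVE_DISTANCE_BINS = BinSpec.from_intervals(
    [(0, 2.5), (2.5, 3), (3, 3.5), (3.5, 4.5), (4.5, 6), (6, 12)]
)
#: Bins of the electrostatic-axis dim-0 count features.
ELECTROSTATIC_BINS = BinSpec.uniform(0.0, 1.0, 10, closure="(]", last="()")
#: Bins of ligand alpha-complex count features ([0, 5] Angstrom, width 0.1).
LIGAND_ALPHA_BINS = BinSpec.uniform(0.0, 5.0, 50)
#: Bins used to slice persistence diagrams for ligand slice-statistics.
LIGAND_SLICE_BINS = BinSpec.uniform(0.0, 5.0, 10)
#: Spatial bins of 2-D topological images ([0, 12] Angstrom, 120 bins).
IMAGE_BINS = BinSpec.uniform(0.0, 12.0, 120)


# ---------------------------------------------------------------------------
# Vectorizers
# ---------------------------------------------------------------------------

_STAT_NAMES = ("avg", "std", "max", "min", "sum", "cnt")


@dataclass
class FeatureBlock:
    """A named numeric feature vector."""

    values: np.ndarray
    schema: list[str]
    group_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.schema):
            raise ValueError("schema/value length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def concat(cls, blocks: Sequence["FeatureBlock"], group_id: str = "") -> "FeatureBlock":
        if not blocks:
            return cls(np.zeros(0), [], group_id)
        values = np.concatenate([b.values for b in blocks])
        schema = [name for b in blocks for name in b.schema]
        return cls(values, schema, group_id)

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(",".join(self.schema) + "\n")
            fh.write(",".join(f"{v:.10g}" for v in self.values) + "\n")


def counts_in_bins(
    b: Barcode, bins: BinSpec, dim: int
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Per-bin (birth, death, persistence-overlap) counts for one dimension.

    The birth vector is ``None`` for dimension 0 (all dim-0 bars are born
    at the filtration origin). An OPEN death falls in no death bin, but the
    bar overlaps every bin to the right of its birth.
    """
    bars = b.of_dim(dim)
    n = len(bins)
    births = np.zeros(n)
    deaths = np.zeros(n)
    overlaps = np.zeros(n)
    for bar in bars:
        for i in range(n):
            l, r = bins.intervals[i]
            if bins.contains(i, bar.birth):
                births[i] += 1
            if not bar.is_open and bins.contains(i, bar.death):
                deaths[i] += 1
            if bar.birth <= r and bar.death >= l:
                overlaps[i] += 1
    return (None if dim == 0 else births), deaths, overlaps


def _stats(values: Sequence[float]) -> np.ndarray:
    if len(values) == 0:
        return np.zeros(len(_STAT_NAMES))
    arr = np.asarray(values, dtype=float)
    # population standard deviation: a singleton set has spread zero
    return np.array(
        [arr.mean(), arr.std(ddof=0), arr.max(), arr.min(), arr.sum(), len(arr)]
    )


def barcode_statistics(b: Barcode, dim: int, group_id: str = "") -> FeatureBlock:
    """Statistics blocks for one homology dimension.

    Dimension 0 contributes the Death block only (6 values); dimensions 1
    and 2 contribute Birth (6), Death (6) and Persistence (8: the six
    statistics plus the birth and death of the longest bar). OPEN bars are
    closed at the barcode cap before statistics are taken.
    """
    bars = [bar.capped(b.cap) for bar in b.of_dim(dim)]
    births = [bar.birth for bar in bars]
    deaths = [bar.death for bar in bars]
    pers = [bar.persistence for bar in bars]
    prefix = f"d{dim}"
    if dim == 0:
        schema = [f"{prefix}|death|{s}" for s in _STAT_NAMES]
        return FeatureBlock(_stats(deaths), schema, group_id)
    longest = max(bars, key=lambda bar: bar.persistence) if bars else None
    extra = np.array([longest.birth, longest.death]) if longest else np.zeros(2)
    values = np.concatenate([_stats(births), _stats(deaths), _stats(pers), extra])
    schema = (
        [f"{prefix}|birth|{s}" for s in _STAT_NAMES]
        + [f"{prefix}|death|{s}" for s in _STAT_NAMES]
        + [f"{prefix}|pers|{s}" for s in _STAT_NAMES]
        + [f"{prefix}|pers|longest_birth", f"{prefix}|pers|longest_death"]
    )
    return FeatureBlock(values, schema, group_id)


def slice_statistics(
    b: Barcode, axis: str, bins: BinSpec, dim: int, group_id: str = ""
) -> FeatureBlock:
    """Statistics of diagram slices along one axis.

    Death-sliced bars are summarized by Birth statistics, birth-sliced by
    Death statistics, and persistence-sliced by both.
    """
    if axis not in ("birth", "death", "persistence"):
        raise ValueError(f"unknown slicing axis {axis!r}")
    bars = [bar.capped(b.cap) for bar in b.of_dim(dim)]
    key = {
        "birth": lambda bar: bar.birth,
        "death": lambda bar: bar.death,
        "persistence": lambda bar: bar.persistence,
    }[axis]
    complement = {"birth": ("death",), "death": ("birth",), "persistence": ("birth", "death")}[
        axis
    ]
    blocks: list[FeatureBlock] = []
    for i in range(len(bins)):
        in_slice = [bar for bar in bars if bins.contains(i, key(bar))]
        for coord in complement:
            values = [getattr(bar, coord) for bar in in_slice]
            schema = [
                f"d{dim}|{axis}-slice{i}|{coord}|{s}" for s in _STAT_NAMES
            ]
            blocks.append(FeatureBlock(_stats(values), schema, group_id))
    return FeatureBlock.concat(blocks, group_id)


# ---------------------------------------------------------------------------
# 2-D topological images
# ---------------------------------------------------------------------------

#: Fixed channel order of the eight per-structure count maps.
CHANNELS_8 = (
    "Fd(B0)", "Fp(B0)",
    "Fb(B1)", "Fd(B1)", "Fp(B1)",
    "Fb(B2)", "Fd(B2)", "Fp(B2)",
)


@dataclass
class TopoImage:
    """(bins x combinations x channels) count tensor.

    Eight channels for a single structure; sixteen for a complex, where
    channels 8-15 hold the complex-minus-protein count differences.
    """

    tensor: np.ndarray
    bins: BinSpec
    ordering: list[str]
    channels: list[str]

    def save(self, path: str) -> None:
        """Dense binary tensor (.npy) with a JSON sidecar describing axes."""
        np.save(path, self.tensor)
        sidecar = {
            "bins": [list(iv) for iv in self.bins.intervals],
            "ordering": self.ordering,
            "channels": self.channels,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def _channel_stack(b: Barcode, bins: BinSpec) -> np.ndarray:
    cols = []
    for dim in (0, 1, 2):
        births, deaths, overlaps = counts_in_bins(b, bins, dim)
        if dim == 0:
            cols.extend([deaths, overlaps])
        else:
            cols.extend([births, deaths, overlaps])
    return np.stack(cols, axis=-1)  # (bins, 8)


def build_2d_image(
    barcodes: Mapping[str, Barcode],
    bins: BinSpec,
    ordering: Sequence[str],
    protein_barcodes: Mapping[str, Barcode] | None = None,
) -> TopoImage:
    """Stack per-combination count channels into a topological image.

    ``barcodes`` maps combination labels to barcodes holding dims 0-2.
    With ``protein_barcodes`` (complex mode) eight difference channels
    (complex counts minus protein-only counts) are appended, for sixteen
    channels total.
    """
    missing = [c for c in ordering if c not in barcodes]
    if missing:
        raise ValueError(f"missing combinations: {missing}")
    planes = []
    for combo in ordering:
        plane = _channel_stack(barcodes[combo], bins)
        if protein_barcodes is not None:
            if combo not in protein_barcodes:
                raise ValueError(f"missing protein combination: {combo}")
            diff = plane - _channel_stack(protein_barcodes[combo], bins)
            plane = np.concatenate([plane, diff], axis=-1)
        planes.append(plane)
    tensor = np.stack(planes, axis=1)  # (bins, combos, channels)
    channels = list(CHANNELS_8)
    if protein_barcodes is not None:
        channels += [f"diff:{c}" for c in CHANNELS_8]
    return TopoImage(tensor, bins, list(ordering), channels)


# ---------------------------------------------------------------------------
# Element combination lists
# ---------------------------------------------------------------------------


def _with_h(combos: Sequence[str]) -> list[str]:
    return list(combos) + [c + "H" for c in combos]


_CNOS_SUBSETS = [
    "C", "N", "O", "S",
    "CN", "CO", "CS", "NO", "NS", "OS",
    "CNO", "CNS", "COS", "NOS", "CNOS",
]

#: 32 ligand combinations: the 15 nonempty subsets of {C,N,O,S} plus the
#: all-heavy-element set, each with and without hydrogen.
LIGAND_COMBINATIONS_32 = tuple(_with_h(_CNOS_SUBSETS + ["CNOSPFClBrI"]))
#: 36 ligand combinations: the 32 plus the carbon-halogen pairs.
LIGAND_COMBINATIONS_36 = LIGAND_COMBINATIONS_32 + ("CCl", "CClH", "CBr", "CBrH")
#: The five combinations used for barcode-space KNN similarity.
KNN_COMBINATIONS = ("CNOS", "CNOSPFClBrI", "NOH", "CNO", "CNOSPFClBrIH")

_PROTEIN_8 = ("C", "N", "O", "S", "CN", "CO", "NO", "CNO")
_LIGAND_20 = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I",
    "CN", "CO", "CS", "NO", "NS", "OS",
    "CNO", "CNS", "COS", "NOS", "CNOS",
)
#: 160 interactive combinations (8 protein x 20 ligand element sets).
INTERACTIVE_PAIRS_160 = tuple(product(_PROTEIN_8, _LIGAND_20))
#: 36 single-element interactive pairs ({C,N,O,S} x {C,N,O,S,P,F,Cl,Br,I}).
INTERACTIVE_PAIRS_36 = tuple(
    product(("C", "N", "O", "S"), ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I"))
)
#: 50 electrostatic interactive pairs (hydrogens included on both sides).
INTERACTIVE_PAIRS_50 = tuple(
    product(("C", "N", "O", "S", "H"), ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H"))
)
_IMG_PROTEIN_8 = ("C", "N", "O", "CN", "CO", "NO", "CNO", "CNOS")
_IMG_LIGAND_16 = (
    "C", "N", "O", "S",
    "CN", "CO", "CS", "NO", "NS", "OS",
    "CNO", "CNS", "COS", "NOS", "CNOS", "CNOSPFClBrI",
)
#: 128 combinations of the 2-D image representation (8 protein x 16 ligand).
IMAGE_COMBINATIONS_128 = tuple(product(_IMG_PROTEIN_8, _IMG_LIGAND_16))


# ---------------------------------------------------------------------------
# Feature groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureGroup:
    """A registered featurization recipe."""

    name: str
    target: str  # "ligand" | "complex"
    complex_type: str  # "rips" | "alpha"
    scheme: str  # "euclidean" | "multilevel" | "interactive" | "electrostatic_interactive"
    dims: tuple[int, ...]
    combinations: tuple  # element strings, or (protein, ligand) pairs, or tokens
    vectorizer: str  # "counts" | "stats" | "slice_stats"
    bins: BinSpec | None = None
    cap: float = DEFAULT_CAPS["complex"]
    level: int = 1
    c: float = DEFAULT_C


FEATURE_GROUPS: dict[str, FeatureGroup] = {}


def _register(group: FeatureGroup) -> FeatureGroup:
    FEATURE_GROUPS[group.name] = group
    return group


_register(FeatureGroup(
    "A-B012-E-C", "ligand", "alpha", "euclidean", (0, 1, 2),
    LIGAND_COMBINATIONS_32, "counts", LIGAND_ALPHA_BINS,
))
_register(FeatureGroup(
    "A-B012-E-S", "ligand", "alpha", "euclidean", (0, 1, 2),
    LIGAND_COMBINATIONS_32, "stats",
))
_register(FeatureGroup(
    "A-B012-E-SS", "ligand", "alpha", "euclidean", (0, 1, 2),
    LIGAND_COMBINATIONS_32, "slice_stats", LIGAND_SLICE_BINS,
))
_register(FeatureGroup(
    "R-B012-E-S", "ligand", "rips", "euclidean", (0, 1, 2),
    LIGAND_COMBINATIONS_36, "stats", cap=DEFAULT_CAPS["complex"],
))
_register(FeatureGroup(
    "R-B012-M1-S", "ligand", "rips", "multilevel", (0, 1, 2),
    LIGAND_COMBINATIONS_36, "stats", cap=DEFAULT_CAPS["complex"], level=1,
))
_register(FeatureGroup(
    "R-B0-I-C", "complex", "rips", "interactive", (0,),
    INTERACTIVE_PAIRS_160, "counts", INTERACTIVE_DISTANCE_BINS,
    cap=DEFAULT_CAPS["interactive"],
))
_register(FeatureGroup(
    "R-B0-I-BP", "complex", "rips", "interactive", (0,),
    INTERACTIVE_PAIRS_36, "counts", INTERACTIVE_DISTANCE_BINS,
    cap=DEFAULT_CAPS["interactive"],
))
_register(FeatureGroup(
    "R-B0-CI-C", "complex", "rips", "electrostatic_interactive", (0,),
    INTERACTIVE_PAIRS_50, "counts", ELECTROSTATIC_BINS,
    cap=DEFAULT_CAPS["electrostatic"],
))
_register(FeatureGroup(
    "R-B0-CI-S", "complex", "rips", "electrostatic_interactive", (0,),
    INTERACTIVE_PAIRS_50, "stats", cap=DEFAULT_CAPS["electrostatic"],
))
_register(FeatureGroup(
    "A-B12-E-S", "complex", "alpha", "euclidean", (1, 2),
    ("heavy", "C"), "stats",
))


def _selection(group: FeatureGroup, combo) -> ElementSelection:
    if group.target == "ligand":
        return ElementSelection.ligand(combo)
    if isinstance(combo, tuple):
        return ElementSelection.pair(*combo)
    # whole-complex selection (same element set on both sides)
    return ElementSelection(
        protein_elements=_side(combo), ligand_elements=_side(combo)
    )


def _side(combo: str):
    from .structures import _parse_elements

    return _parse_elements(combo)


def combination_label(group: FeatureGroup, combo) -> str:
    return _selection(group, combo).label


def combo_barcode(
    struct: Molecule | ComplexStructure, group: FeatureGroup, combo
) -> Barcode:
    """Barcode of one element combination under a group's filtration scheme."""
    sel = _selection(group, combo)
    atoms = select_atoms(struct, sel)
    prov = (getattr(struct, "id", "") or "complex", sel.label, group.scheme)
    if not atoms:
        return Barcode([], group.cap, group.complex_type, prov)
    max_dim = max(group.dims)
    if group.complex_type == "alpha":
        coords = np.array([a.coords for a in atoms])
        if len(atoms) > 1 and np.allclose(coords, coords[0]):
            return Barcode([], group.cap, "alpha", prov)
        return alpha_persistence(coords, max_dim=max_dim, provenance=prov)
    if group.scheme == "euclidean":
        matrix = euclidean_matrix(atoms)
    elif group.scheme == "multilevel":
        if not isinstance(struct, Molecule):
            raise ValueError("multilevel scheme expects a single molecule")
        graph = build_bond_graph(struct, "from_records" if struct.bonds else "distance_cutoff")
        hop = graph.hop_matrix()
        idx = [k for k, a in enumerate(struct.atoms) if sel.matches(a)]
        # hop distances are taken in the full molecule, then restricted
        sub = hop[np.ix_(idx, idx)]
        matrix = multilevel_matrix(atoms, _SubsetBondGraph(sub), level=group.level)
    else:
        has_p = any(a.role == "protein" for a in atoms)
        has_l = any(a.role == "ligand" for a in atoms)
        if not (has_p and has_l):
            return Barcode([], group.cap, "rips", prov)
        if group.scheme == "interactive":
            base = euclidean_matrix(atoms)
        elif group.scheme == "electrostatic_interactive":
            base = electrostatic_matrix(atoms, c=group.c)
        else:
            raise ValueError(f"unknown scheme {group.scheme!r}")
        matrix = interactive_matrix(atoms, base=base)
    return rips_persistence(matrix, max_dim=max_dim, cap=group.cap, provenance=prov)


class _SubsetBondGraph:
    """Adapter exposing a precomputed hop-distance submatrix as a BondGraph."""

    def __init__(self, hop_submatrix: np.ndarray):
        self._hops = hop_submatrix
        self.n_atoms = hop_submatrix.shape[0]

    def hop_matrix(self) -> np.ndarray:
        return self._hops


def _vectorize_combo(b: Barcode, group: FeatureGroup, label: str) -> FeatureBlock:
    blocks: list[FeatureBlock] = []
    for dim in group.dims:
        if group.vectorizer == "counts":
            births, deaths, overlaps = counts_in_bins(b, group.bins, dim)
            nbin = len(group.bins)
            if dim == 0:
                blocks.append(FeatureBlock(
                    deaths, [f"{label}|d0|death|bin{i}" for i in range(nbin)], group.name
                ))
            else:
                blocks.append(FeatureBlock(
                    np.concatenate([births, deaths, overlaps]),
                    [f"{label}|d{dim}|{kind}|bin{i}"
                     for kind in ("birth", "death", "pers")
                     for i in range(nbin)],
                    group.name,
                ))
        elif group.vectorizer == "stats":
            block = barcode_statistics(b, dim, group.name)
            blocks.append(FeatureBlock(
                block.values, [f"{label}|{s}" for s in block.schema], group.name
            ))
        elif group.vectorizer == "slice_stats":
            for axis in ("birth", "death", "persistence"):
                block = slice_statistics(b, axis, group.bins, dim, group.name)
                blocks.append(FeatureBlock(
                    block.values, [f"{label}|{s}" for s in block.schema], group.name
                ))
        else:
            raise ValueError(f"unknown vectorizer {group.vectorizer!r}")
    return FeatureBlock.concat(blocks, group.name)


def assemble_features(
    struct: Molecule | ComplexStructure, group: str | FeatureGroup
) -> FeatureBlock:
    """Concatenated feature vector of a registered group for one structure."""
    if isinstance(group, str):
        if group not in FEATURE_GROUPS:
            raise KeyError(f"unknown feature group {group!r}")
        group = FEATURE_GROUPS[group]
    if group.target == "complex" and not isinstance(struct, ComplexStructure):
        raise ValueError(f"group {group.name} expects a protein-ligand complex")
    if group.target == "ligand" and isinstance(struct, ComplexStructure):
        struct = struct.ligand
    blocks = []
    for combo in group.combinations:
        label = combination_label(group, combo)
        b = combo_barcode(struct, group, combo)
        blocks.append(_vectorize_combo(b, group, label))
    return FeatureBlock.concat(blocks, group.name)


def feature_schema(group: str | FeatureGroup) -> list[str]:
    """Schema of a group without touching any structure (pure in the config)."""
    if isinstance(group, str):
        group = FEATURE_GROUPS[group]
    empty = Barcode([], group.cap, group.complex_type)
    names: list[str] = []
    for combo in group.combinations:
        label = combination_label(group, combo)
        names.extend(_vectorize_combo(empty, group, label).schema)
    return names
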