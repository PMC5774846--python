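"""Element bookkeeping: symbol normalization and atomic radii.

Radii come from RDKit's periodic table so that bond perception and
correlation-kernel scales use the same standard values a cheminformatics
practitioner would expect (covalent radii for bond detection, van der
Waals radii for kernel scale parameters).
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

_PT = Chem.GetPeriodicTable()

#: Elements commonly encountered in protein-ligand systems. Parsing accepts
#: any symbol RDKit knows; this set is only used for quick sanity checks.
COMMON_ELEMENTS = frozenset(
    ["H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I",
     "B", "Se", "Na", "K", "Ca", "Mg", "Zn", "Fe", "Mn", "Cu", "Co"]
)


def normalize_symbol(raw: str) -> str:
    """Normalize an element symbol to canonical capitalization (``CL`` -> ``Cl``).

    Raises ``ValueError`` for strings RDKit does not recognize as an element.
    """
    s = raw.strip()
    if not s:
        raise ValueError("empty element symbol")
    s = s[0].upper() + s[1:].lower()
    if _PT.GetAtomicNumber(s) == 0 and s != "X":
        raise ValueError(f"unrecognized element symbol: {raw!r}")
    return s


@lru_cache(maxsize=None)
def covalent_radius(symbol: str) -> float:
    """Covalent radius in Angstrom."""
    return float(_PT.GetRcovalent(normalize_symbol(symbol)))


@lru_cache(maxsize=None)
def vdw_radius(symbol: str) -> float:
    """Van der Waals radius in Angstrom."""
    return float(_PT.GetRvdw(normalize_symbol(symbol)))
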