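"""Electrostatic interactive persistence of a protein-ligand complex.

Builds one synthetic pocket-compound complex with planted complementary
contacts, filters the cross-role pairs by the charge-aware sigmoid
correlation (c = 100), and prints where the dim-0 components merge on the
[0, 1] electrostatic axis.
"""

from topomol import (
    electrostatic_matrix,
    interactive_matrix,
    make_screen_set,
    rips_persistence,
)

(cx, target, label), *_ = make_screen_set(1, 1, 0, effect=1.0, seed=5)
atoms = cx.atoms
print(f"{target} {label}: {len(cx.protein)} pocket atoms + {len(cx.ligand)} ligand atoms")

base = electrostatic_matrix(atoms, c=100)
matrix = interactive_matrix(atoms, base=base)
barcode = rips_persistence(matrix, max_dim=0, cap=1.0)

deaths = sorted(b.death for b in barcode.of_dim(0) if not b.is_open)
print("dim-0 merge values on the electrostatic axis:")
print("  lowest five:", [round(d, 3) for d in deaths[:5]])
low = sum(1 for d in deaths if d < 0.1)
print(f"  {low} merges below 0.1 (strong opposite-charge contacts)")

# Values near 0 are attractive (opposite-sign) close contacts, values near
# 0.5 are weak or distant interactions; the planted hydrogen-bond-like
# contacts of an active compound appear as merges far below 0.5.
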