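"""Multi-level persistence distinguishes conformers that plain Rips cannot.

For a small molecule, the ordinary distance matrix yields dim-0 bars that
only record covalent bond lengths, so two slightly different conformers
look (nearly) identical. Deleting bonded pairs from the filtration (the
level-1 matrix) exposes non-covalent contacts and enriches dimensions 1-2,
where the 0.3 Angstrom perturbation becomes clearly visible.
"""

from topomol import (
    build_bond_graph,
    euclidean_matrix,
    make_conformer_pair,
    multilevel_matrix,
    rips_persistence,
    wasserstein_distance,
)

mol, conf = make_conformer_pair(n_atoms=10, magnitude=0.3, seed=3)
print(f"{mol.id}: 10 atoms, conformer jittered by <= 0.3 A per atom")

for name, matrix_of in (
    ("euclidean", lambda m: euclidean_matrix(m.atoms)),
    ("level-1", lambda m: multilevel_matrix(m.atoms, build_bond_graph(m), 1)),
):
    b1 = rips_persistence(matrix_of(mol), max_dim=2, cap=12)
    b2 = rips_persistence(matrix_of(conf), max_dim=2, cap=12)
    d = {k: wasserstein_distance(b1, b2, dim=k) for k in (0, 1, 2)}
    bars = {k: len(b1.of_dim(k)) for k in (0, 1, 2)}
    print(f"{name:10s} bars/dim {bars}  d2 per dim "
          f"{ {k: round(v, 3) for k, v in d.items()} }")

# The euclidean filtration carries few higher-dimensional bars and its
# dim-0 distance mostly reflects bond lengths, which barely move; the
# level-1 filtration grows substantially more dim-1/2 bars whose combined
# Wasserstein distance is several times larger — the enrichment that makes
# small-molecule conformers separable.
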