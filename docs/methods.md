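# Methods

## Model

Atoms of a structure are a finite point set with chemical labels: element
symbol, optional partial charge (elementary-charge units), and a role
(protein or ligand). A *filtration matrix* assigns every atom pair a value
on a filtration axis, plus an exclusion mask for pairs that must never
form an edge. The Vietoris–Rips complex at scale *r* contains a simplex
whenever all pairwise values among its vertices are ≤ *r*; sweeping *r*
and tracking homology over ℤ₂ yields barcodes in dimensions 0–2
(components, rings, cavities). Because the Rips construction only needs a
symmetric matrix, chemically modified "distances" are admissible even when
they violate the triangle inequality.

Filtration variants:

- **Euclidean** `M = (d_ij)` in Å.
- **Multi-level** `M̃ⁿ`: pairs with covalent hop distance `D(i,j) ≤ n`
  are excluded (default `n = 1`, i.e. bonded pairs removed). Hop distances
  are computed by BFS on the molecule's full bond graph and then
  restricted to the selected atom subset, so element selection never
  shortens bond paths.
- **Interactive** `M̂`: within-group pairs excluded; the base matrix may
  itself be Euclidean or electrostatic (composition gives the charged
  interface filtration).
- **Correlation** `1 − Φ(d_ij; η_ij, ν)` with the Lorentz kernel
  `Φ = 1/(1 + (d/η)^ν)`; axis [0, 1]. The per-pair scale `η_ij` defaults
  to the sum of the two atoms' van der Waals radii (the kernel scale is
  "related to the radii"; the vdW sum is the standard concrete choice and
  is overridable per call). The per-atom rigidity index
  `μ_i = Σ_{j≠i} Φ(d_ij)` is exposed as a diagnostic.
- **Electrostatic** `Φ = 1/(1 + exp(−c·qᵢqⱼ/d))`, `c = 100` by default,
  distances in Å unscaled. With `c > 0`, attractive pairs map below 0.5,
  repulsive above, weak interactions near 0.5; filtration proceeds in
  increasing Φ on [0, 1]. A charge-density evaluator
  `μ_c(r) = Σ_j q_j exp(−‖r−r_j‖/η_j)` is provided as a scalar field only
  (no cubical filtration is built).

The **alpha** filtration is the Delaunay triangulation with each simplex
entering at radius equal to half its longest edge ("every 1-face has
length ≤ 2r"). On the radius axis, alpha dim-0 deaths are therefore
exactly half the Euclidean-Rips dim-0 deaths (the minimum spanning tree is
a subgraph of the Delaunay graph), which the tests exploit as a law. For
four or fewer points, and for small degenerate inputs Qhull rejects, the
complete complex is substituted (identical to the Delaunay complex at
those sizes in general position).

## Persistence computation

Production path: simplices (up to dimension 3, i.e. one above the highest
reported homology dimension) are enumerated from the edge graph, sorted by
(value, dimension, vertex tuple), and the ℤ₂ boundary matrix is reduced in
filtration order with columns packed into Python integers (bitmask XOR,
lowest-one pivoting). Zero-persistence pairs are dropped; classes alive at
the filtration cap are reported OPEN (death = +∞). Default caps: 12 Å for
complex/ligand Rips features, 50 Å for interactive distance features, 1.0
for the electrostatic axis, 5 Å for ligand alpha features — matching the
bin ranges of the registered feature recipes.

Two deliberately naive oracles verify the implementation: Kruskal
union-find over finite edges (dim 0; merge values are deaths) and a dense
boolean-matrix Gaussian elimination over an explicit filtered complex (all
dims, ≤ a few hundred simplices). The test suite asserts bar-multiset
equality on randomized inputs against both.

Tie-breaking: simultaneous simplices are ordered by (value, dim, vertex
tuple); barcodes are multiset-identical under any admissible order, which
the oracle comparison enforces. Excluded pairs are omitted from complex
construction entirely — equivalent to any `d∞` beyond the cap, without
choosing a magic number.

## Vectorization

- **Counts in bins**: per bin, the number of births, deaths, and bars
  whose interval overlaps the bin (`b ≤ r_i` AND `d ≥ l_i`). The overlap
  (AND) reading is used deliberately: the OR form is satisfied by nearly
  every bar and carries no information. Dim-0 features use death (and,
  in images, overlap) counts only, since all dim-0 bars are born at 0.
  An OPEN death falls in no death bin but overlaps every bin right of its
  birth.
- **Barcode statistics**: avg/std/max/min/sum/count of the Birth, Death
  and Persistence multisets; the Persistence block appends the longest
  bar's birth and death. Dim 0 contributes the Death block only. std is
  the population standard deviation (singleton sets have spread 0); empty
  sets yield all-zero blocks. OPEN bars are closed at the cap first.
- **Slice statistics**: the diagram is cut into bins along the birth,
  death or persistence axis; death slices are summarized by Birth
  statistics, birth slices by Death statistics, persistence slices by
  both.
- **2-D topological images**: per element combination, eight channels
  (`F_d(B⁰), F_p(B⁰), F_b/F_d/F_p(B¹), F_b/F_d/F_p(B²)`) over 120 bins on
  [0, 12] Å; complex mode appends the complex-minus-protein differences
  for 16 channels (difference channels may be negative). Combinations are
  ordered by importance scores obtained from a tree-ensemble fitted on
  training data (`rank_combinations`); the order must be persisted and
  reused at inference.

Registered feature groups reproduce the standard recipes: the 32-
combination ligand list (the 15 nonempty subsets of {C,N,O,S} plus the
all-heavy set, each with and without H) and its 36-combination extension
(+ CCl/CClH/CBr/CBrH); 160 = 8×20 and 36 = 4×9 interactive pairs with the
bin list {[0,2.5), [2.5,3), [3,3.5), [3.5,4.5), [4.5,6), [6,12]}; 50 =
5×10 electrostatic pairs with ten 0.1-wide bins on (0,1); the 128 = 8×16
image list; alpha dims 1–2 statistics over all-heavy and all-carbon
selections. Where a recipe's bin count is not pinned by its definition
(counts on [0, 5] for ligand alpha features), 50 bins of width 0.1 Å are
used and are configurable.

## Barcode metrics and learners

Bottleneck and *p*-Wasserstein distances (default `p = 2`) between capped
barcodes are computed exactly: Wasserstein via the augmented assignment
problem (each bar may match a diagonal copy at cost `λ = (d−b)/2`;
`scipy.optimize.linear_sum_assignment` on the `Δ^p`/`λ^p` cost matrix),
bottleneck via binary search over candidate costs with bipartite matching
feasibility. Unmatched bars enter the p-power sum as `λ^p` with no factor
adjustments. A brute-force enumeration over all partial bijections is the
oracle for small inputs. Molecule similarity is the flat mean of
2-Wasserstein distances over (five ligand element combinations) ×
(Euclidean, level-1) × (dims 0–2); the flat mean (rather than nested
averaging) is the simplest reading and is configurable.

Learners: KNN regression on the precomputed barcode distance matrix
(k = 3, unweighted mean, stable-order tie-breaks, leave-one-out mode);
scikit-learn tree ensembles behind registered configurations — regression
GBT (20000 trees, depth 8, learning rate 0.005, subsample 0.7, sqrt
features) and screening classifiers (GBT: 2000 trees, subsample 0.5,
learning rate 0.01, 100:1 positive:negative weight applied as sample
weights since the backend GBT takes no class_weight; RF/ET: 2000 trees,
balanced-subsample). The screening voter averages positive-class
probabilities; `consensus_average` merges arbitrary prediction vectors.

Screening metrics: the rank-based AUC `1 − (1/N_a) Σ N_dⁱ/N_d` with tied
decoys counting one half (Mann–Whitney convention; cross-checked against
`sklearn.roc_auc_score`), and `EF_x% = (N_a^{x%}/N^{x%})·(N/N_a)` with
`N^{x%} = ⌈xN/100⌉` (ceiling; the alternatives differ negligibly at
realistic library sizes but are distinguishable on toy sets).

## Synthetic fixtures: what they emulate and what they do not

Toy molecules are connected random bond graphs (bond lengths 1.3–1.8 Å,
≥ 1.2 Å non-bonded separation, compact growth within ~2.4 Å of the seed
atom, near-zero net charge) — they emulate the sizes, element palettes and
charge scales of drug-like ligands but have no valence rules, torsional
preferences or aromaticity. The screening fixture builds one rigid
icosahedral cage of 12 protein-role atoms per target (radius 7 Å, random
orientation and element assignment, charge magnitudes 0.25–0.5): the
simplest geometry with non-trivial topology in dims 1–2. Actives receive
three hydrogen-bond-like contacts — a polar (N/O where available) pocket
atom paired with the nearest polar ligand atom moved to 2.8–3.5 Å with an
opposite-sign charge — while decoys receive the same transformation drawn
from a randomized regime (3.8–5.5 Å, random charge). The effect parameter
interpolates between the two regimes; at effect 0 the construction is
label-independent, so classes are exchangeable and any classifier's AUC
has expectation 0.5. Consequently, passing tests demonstrate that the
pipeline recovers a planted interface signal and is calibrated under the
null; they say nothing about docking-pose quality, conformational
flexibility, or decoy property-matching in real libraries.

Generator defaults (4 targets × 10 actives + 30 decoys) are the package's
study conditions: multiple pockets are required for leave-one-target-out
transfer, since each pocket expresses the contact signal in different
element-pair feature columns.

## Problem sizes and numerical choices

Tests and examples run Rips up to dim 2 on ≤ ~15-atom selections, alpha on
arbitrary ligand sizes (Delaunay keeps the complex linear), and screening
experiments with 160 complexes and 100–300-tree voters — sizes chosen so
the whole suite completes in well under an hour on one core while every
assertion remains a genuine computation. The registered model defaults
keep the reference ensemble sizes (2000/20000); desk-scale runs override
`n_estimators` explicitly. Determinism: every stochastic component takes a
seed (`numpy.random.default_rng`; scikit-learn `random_state`), and fixed
seed + inputs reproduce predictions bit-wise per backend contract.

## Known limitations

- Homology dimensions above 2, zigzag and genuinely multiparameter
  persistence are out of scope; the 2-D images are stacked one-parameter
  computations.
- The alternative charge correlation `q_i q_j exp(−d/η)` (different
  filtration domain) and cubical filtration of the charge density are not
  implemented.
- The deep CNN learners that can consume the topological images are not
  part of the package; the consensus operator accepts externally produced
  prediction vectors instead.
- Bond perception without bond records uses the covalent-radius rule
  (≤ 1.3 × sum of covalent radii) — adequate for organic structures, not
  for metal centers.
- Parsers keep the first altLoc, skip waters, and do not repair,
  protonate or charge structures; Mol2 charges (or a user table) are the
  only charge sources.
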