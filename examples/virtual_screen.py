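"""A desk-scale virtual screen on the synthetic active/decoy benchmark.

Generates four pocket targets with 10 actives and 30 decoys each, computes
interactive-distance and electrostatic count features for every complex,
trains the three-member voting classifier (GBT + random forest + extra
trees) per leave-one-target-out round, and reports AUC and enrichment.
"""

from topomol import auc, make_screen_set
from topomol.pipeline import run_screening_experiment

records = make_screen_set(n_targets=4, n_actives=10, n_decoys=30,
                          effect=1.0, seed=1)
print(f"screen set: {len(records)} complexes over 4 targets")

report, pooled = run_screening_experiment(records, seed=1, n_estimators=300)
print(report.to_string(index=False))
print(f"pooled AUC over all held-out targets: {auc(pooled):.3f}")

# AUC = 1 is a perfect ranking and 0.5 is chance; EF2% is how many-fold
# actives are enriched among the top 2% ranked compounds. With the planted
# complementary contacts (effect 1.0) the ensemble ranks actives far above
# decoys on targets it has never seen.
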