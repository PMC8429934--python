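"""Discover infiltration patterns by consensus clustering and pick k.

Clusters the per-sample cell-fraction profiles of a planted 3-pattern
cohort with subsampled PAM runs, sweeps k = 2..6, and shows that the
delta-area elbow of the consensus CDF recovers the planted k.
"""

from sklearn.metrics import adjusted_rand_score

from ici_landscape.pattern_discovery import consensus_sweep, select_k
from ici_landscape.synthetic_cohort import CohortConfig, simulate_expression

cfg = CohortConfig(n_samples=150, n_genes=200, markers_per_type=5, seed=3)
_, fractions, truth, _, _ = simulate_expression(cfg)

results = consensus_sweep(fractions, range(2, 7), reps=200, p_item=0.8, seed=0)
sel = select_k(results)

print("area under the consensus CDF per k:",
      {k: round(r.area_under_cdf, 3) for k, r in results.items()})
print("delta-area per k:", {k: round(v, 3) for k, v in sel.delta_area.items()})
print(f"chosen k = {sel.chosen_k}")
ari = adjusted_rand_score(truth.to_numpy(), results[sel.chosen_k].assignments.to_numpy())
print(f"ARI against the planted patterns at k={sel.chosen_k}: {ari:.3f}")
# The delta-area drops sharply once k exceeds the planted 3 patterns; an
# ARI of 1.0 means the consensus assignment matches the truth exactly.
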