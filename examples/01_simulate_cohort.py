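"""Generate a synthetic tumor cohort with planted ground truth.

Builds a 150-sample, 800-gene cohort whose expression is a noisy convex
mixture of 8 leukocyte programs with three planted infiltration patterns,
then prints what was planted. The written files (expression TSV, clinical
TSV, MAF, marker GMT, ground-truth JSON) are the inputs every later stage
consumes.
"""

from ici_landscape.synthetic_cohort import CohortConfig, simulate_cohort, write_cohort

cfg = CohortConfig(n_samples=150, n_genes=800, markers_per_type=15, seed=1)
cohort = simulate_cohort(cfg)
paths = write_cohort(cohort, "scratch/example_cohort")

print(f"expression: {cohort.expression.shape[0]} genes x {cohort.expression.shape[1]} samples")
print(f"planted patterns: {cohort.true_cluster.value_counts().sort_index().to_dict()}")
print(f"censoring fraction: {(cohort.clinical['os_event'] == 0).mean():.2f}")
print(f"MAF records: {len(cohort.maf)}")
print("files:", ", ".join(sorted(paths)))
# The pattern counts show the planted 3-cluster mixing structure; the
# censoring fraction reflects the configured 30% independent censoring.
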