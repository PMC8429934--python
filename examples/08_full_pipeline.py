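"""Run the whole analysis end-to-end from one config.

Simulates a cohort, then executes batch correction, TIME profiling,
consensus pattern discovery, ICI scoring, survival analysis, GSEA and the
mutation landscape as one pipeline with plain-file handoffs, and prints the
per-stage status and timings recorded in the run manifest.
"""

import json
from pathlib import Path

from ici_landscape.pipeline import run_pipeline

out = Path("scratch/example_pipeline")
manifest = run_pipeline(
    {
        "simulate": {"n_samples": 120, "n_genes": 600, "markers_per_type": 12},
        "profile": {"n_perm": 50},
        "cluster": {"reps": 100, "k_max": 5},
        "score": {"n_trees": 200, "boruta_max_iter": 50},
        "gsea": {"n_perm": 100},
    },
    out,
    seed=8,
)

for stage, info in manifest["stages"].items():
    print(f"{stage:10s} {info['status']:10s} {info.get('seconds', 0):6.1f}s")
summary = json.loads((out / "survival_summary.json").read_text())
print("log-rank between ICI score groups: p =", f"{summary['logrank']['p']:.2e}")
print("Cox covariates kept by backward-AIC:", summary["cox"]["covariates"])
# Every stage writes plain TSV/JSON into the run directory, so any stage
# can be inspected or re-run on its own; the manifest records checksums
# for reproducibility.
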