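"""End-to-end run: simulate -> QC -> consolidate -> label -> train -> report.

Run:  python examples/05_full_pipeline.py
"""

import tempfile
from pathlib import Path

from cytosv import CohortConfig, RunConfig, plant_sv_cohort, run_end_to_end

workdir = Path(tempfile.mkdtemp(prefix="cytosv_example_"))
cohort = plant_sv_cohort(CohortConfig(seed=4), workdir / "cohort")
print(f"simulated {len(cohort.truth.rows)} SVs in {workdir / 'cohort'}")

config = RunConfig.from_cohort(cohort, workdir / "run", importance_repeats=3)
result = run_end_to_end(config)

print("stage counts:", result["manifest"]["stages"]["qc"],
      result["manifest"]["stages"]["consolidate"])
for group in ("TRS", "nonTRS"):
    rep = result["reports"][group]
    print(
        f"{group:6s}: somatic AUC {rep.somatic_auc:.3f}, "
        f"sens {rep.sensitivity:.3f}, spec {rep.specificity:.3f} "
        f"(holdout per class {rep.n_per_class})"
    )
print(f"HTML summary: {workdir / 'run' / 'summary.html'}")

# Outputs: labeled.tsv (class + evidence per SV), features.tsv, one saved
# model and JSON report per group, and a static HTML summary with class
# counts, ROC curves and feature distributions.
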