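"""Simulate a small SV cohort: caller VCFs, databases, and a truth table.

Run:  python examples/01_simulate_cohort.py
"""

import tempfile
from pathlib import Path

from cytosv import CohortConfig, plant_sv_cohort

outdir = Path(tempfile.mkdtemp(prefix="cytosv_example_"))
config = CohortConfig(
    seed=1,
    n_chroms=3, chrom_len=4_000_000, sv_len_range=(1_100_000, 1_900_000),
    n_artifact=12, n_germline=16, n_somatic=10, n_decoy=5,
)
files = plant_sv_cohort(config, outdir)

print(f"cohort written to {outdir}")
print(f"caller VCFs: {sorted(p.name for p in files.caller_vcfs.values())}")
print("planted class counts (class -> svtype -> n):")
for klass, by_type in sorted(files.truth.class_counts().items(), key=str):
    print(f"  {klass}: {dict(sorted(by_type.items()))}")

# Each group (translocation and interval SVs) receives the configured counts:
# -1 = artifact calls, 1 = germline variants, 2 = somatic cytogenetic SVs,
# and 'unlabeled' decoys that match no annotation resource.
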