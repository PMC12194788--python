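"""Consolidate multi-caller calls and label them against databases.

Run:  python examples/02_label_truth_set.py
"""

import tempfile
from pathlib import Path

from cytosv import (
    CohortConfig, LabelContext, apply_basic_qc, build_truth_set,
    consolidate_calls, filter_by_length, plant_sv_cohort, read_caller_vcf,
    read_database,
)

outdir = Path(tempfile.mkdtemp(prefix="cytosv_example_"))
files = plant_sv_cohort(
    CohortConfig(seed=2, n_chroms=3, chrom_len=4_000_000,
                 sv_len_range=(1_100_000, 1_900_000),
                 n_artifact=10, n_germline=14, n_somatic=8, n_decoy=4),
    outdir,
)

# QC each caller's calls, keep the cytogenetic size regime (>= 1 Mb),
# then merge matching calls across callers (90% reciprocal overlap /
# 1 kb breakend distance, single linkage).
per_caller = {}
for caller, path in files.caller_vcfs.items():
    kept, report = apply_basic_qc(read_caller_vcf(path, caller))
    per_caller[caller] = filter_by_length(kept, 1_000_000)
    print(f"{caller}: {report.n_input} calls, {len(per_caller[caller])} kept")
merged = consolidate_calls(per_caller)
print(f"consolidated into {len(merged)} SVs")

databases = (
    read_database(files.germline_panel, "germline_panel")
    + read_database(files.germline_phase3, "germline_phase3")
    + read_database(files.hotspot_a, "somatic_hotspot_A")
    + read_database(files.hotspot_b, "somatic_hotspot_B")
)
donors = read_database(files.donor_vcf, "donor_cohort")
centromeres = read_database(files.reference.centromere_bed, "centromere")
ctx = LabelContext.from_centromere_entries(centromeres)

labeled, summary = build_truth_set(
    merged, databases, donors, ctx, n_donors=files.config.n_donors
)
print("label summary (class -> svtype -> n):")
for klass, by_type in sorted(summary.items(), key=str):
    print(f"  {klass}: {dict(sorted(by_type.items()))}")
example = next(l for l in labeled if l.klass == -1)
print(f"example artifact evidence: {example.evidence}")

# Classes follow the precedence ladder: artifact evidence (flagged database
# entry, high donor frequency, centromeric breakend) beats a PASS germline
# match, which beats a somatic hotspot match.
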