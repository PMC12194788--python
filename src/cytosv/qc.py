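"""Basic SV quality filters and length thresholds.

Three rules, applied in a fixed order so removal reasons are deterministic:
uncertain genotype, incomplete breakpoint information (a missing position or
confidence interval at either end), and missing read evidence (< 1
alternate-supporting read at a breakend). Length filtering keeps interval SVs
at or above a minimum size; translocations have no defined length and are
always kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from cytosv.records import SVRecord

REMOVAL_REASONS = (
    "uncertain_genotype",
    "incomplete_breakpoint",
    "no_read_evidence",
    "below_length",
)

# modeling threshold (100 kb) vs cytogenetic-validation threshold (1 Mb)
MODELING_MIN_LEN = 100_000
CYTOGENETIC_MIN_LEN = 1_000_000


@dataclass
class FilterReport:
    """Counts in, counts kept, and per-reason removal counts."""

    n_input: int = 0
    n_kept: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.n_input == self.n_kept + sum(self.removed.values())


def _failing_rule(rec: SVRecord, strict_reads: bool) -> str | None:
    if rec.genotype == "uncertain":
        return "uncertain_genotype"
    if not (rec.end1.has_ci and rec.end2.has_ci):
        return "incomplete_breakpoint"
    if strict_reads:
        if min(rec.alt_reads) < 1:
            return "no_read_evidence"
    else:
        if max(rec.alt_reads) < 1:
            return "no_read_evidence"
    return None


def apply_basic_qc(
    records: Iterable[SVRecord],
    strict_reads: bool = True,
) -> tuple[list[SVRecord], FilterReport]:
    """Apply the three basic quality rules; return kept records and a report.

    ``strict_reads=True`` requires at least one alternate-supporting read at
    EACH breakend; ``False`` relaxes this to at least one end.
    """
    kept: list[SVRecord] = []
    report = FilterReport()
    for rec in records:
        report.n_input += 1
        reason = _failing_rule(rec, strict_reads)
        if reason is None:
            kept.append(rec)
            report.n_kept += 1
        else:
            report.removed[reason] = report.removed.get(reason, 0) + 1
    return kept, report


def filter_by_length(
    records: Iterable[SVRecord], min_len: int
) -> list[SVRecord]:
    """Keep interval SVs with length >= ``min_len``; TRS records always pass."""
    if min_len <= 0:
        raise ValueError(f"min_len must be positive, got {min_len}")
    out = []
    for rec in records:
        if rec.svtype == "TRS" or (rec.length is not None and rec.length >= min_len):
            out.append(rec)
    return out
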