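"""Per-SV feature extraction: read, breakpoint, and sequence-complexity metrics.

Read metrics follow the two derived formulas ``read_diff = alt - ref`` and
``read_ratio = alt / (alt + ref)`` (undefined at zero depth). Complexity
metrics — k-mer Shannon entropy (k = 1..3), linguistic complexity and GC
content — are computed on the reference context around each breakend
(default ±100 bp), where low-complexity sequence is a known driver of
calling artifacts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, fields as dataclass_fields

from cytosv.matching import RecordLike, _as_record

_VALID = set("ACGT")


def read_diff(alt: int, ref: int) -> int:
    """alt-supporting minus ref-supporting read count."""
    if alt < 0 or ref < 0:
        raise ValueError("read counts must be non-negative")
    return alt - ref


def read_ratio(alt: int, ref: int) -> float | None:
    """Fraction of reads supporting the alternate allele; None at zero depth."""
    if alt < 0 or ref < 0:
        raise ValueError("read counts must be non-negative")
    total = alt + ref
    if total == 0:
        return None
    return alt / total


def _kmer_counts(seq: str, k: int) -> Counter:
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    counts: Counter = Counter()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= _VALID:  # k-mers containing N (or other codes) excluded
            counts[kmer] += 1
    return counts


def shannon_entropy(seq: str, k: int = 1) -> float:
    """Shannon entropy (bits) of the overlapping k-mer distribution."""
    counts = _kmer_counts(seq, k)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in counts.values()) + 0.0


def linguistic_complexity(seq: str, max_k: int = 3) -> float:
    """Vocabulary richness: product over k of observed/possible distinct k-mers.

    For each word size k, the usage ratio is the number of distinct observed
    k-mers over ``min(4^k, L - k + 1)``; the metric is the product over
    k = 1..max_k and lies in (0, 1].
    """
    if len(seq) < max_k:
        raise ValueError(f"sequence of length {len(seq)} shorter than max_k={max_k}")
    product = 1.0
    for k in range(1, max_k + 1):
        counts = _kmer_counts(seq, k)
        possible = min(4**k, len(seq) - k + 1)
        observed = len(counts)
        if observed == 0:  # all windows N-contaminated; no vocabulary signal
            continue
        product *= observed / possible
    return product


def gc_content(seq: str) -> float:
    """G+C fraction over A/C/G/T bases (N excluded); 0.0 for all-N input."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class FeatureVector:
    """The model's input row for one SV; None encodes an absent value."""

    read_diff: int
    read_ratio: float | None
    qual: float
    gq: float
    cipos_width: float | None
    ciend_width: float | None
    log_length: float | None
    n_callers: int
    b1_entropy_k1: float
    b1_entropy_k2: float
    b1_entropy_k3: float
    b1_linguistic_complexity: float
    b1_gc_content: float
    b2_entropy_k1: float
    b2_entropy_k2: float
    b2_entropy_k3: float
    b2_linguistic_complexity: float
    b2_gc_content: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


FEATURE_NAMES = [f.name for f in dataclass_fields(FeatureVector)]


def _breakend_context(reference, chrom: str, pos: int, window: int) -> str:
    """Reference sequence around a breakend, truncated at chromosome ends."""
    if chrom not in reference:
        raise KeyError(f"chromosome {chrom!r} absent from the reference")
    chrom_len = len(reference[chrom])
    lo = max(pos - window, 1)
    hi = min(pos + window, chrom_len)
    # pyfaidx slices are 0-based half-open
    return str(reference[chrom][lo - 1 : hi]).upper()


def extract_features(
    record: RecordLike,
    reference,
    window: int = 100,
    n_callers: int | None = None,
) -> FeatureVector:
    """Compute the full feature vector for one (possibly consolidated) SV.

    ``reference`` is a mapping-style genome accessor (e.g. ``pyfaidx.Fasta``).
    ``n_callers`` defaults to the record's own caller-set size.
    """
    from cytosv.matching import ConsolidatedSV

    if n_callers is None:
        n_callers = (
            len(record.callers)
            if isinstance(record, ConsolidatedSV)
            else len(_as_record(record).callers)
        )
    rec = _as_record(record)
    # callers usually report one count pair duplicated across both ends;
    # averaging recovers the per-record value and is well-defined for TRS
    alt = sum(rec.alt_reads) / 2
    ref = sum(rec.ref_reads) / 2
    alt = int(alt) if alt.is_integer() else alt
    ref = int(ref) if ref.is_integer() else ref

    ctx = {}
    for label, end in (("b1", rec.end1), ("b2", rec.end2)):
        seq = _breakend_context(reference, end.chrom, end.pos, window)
        ctx[label] = {
            "entropy_k1": shannon_entropy(seq, 1),
            "entropy_k2": shannon_entropy(seq, 2),
            "entropy_k3": shannon_entropy(seq, 3),
            "linguistic_complexity": linguistic_complexity(seq, 3),
            "gc_content": gc_content(seq),
        }

    return FeatureVector(
        read_diff=read_diff(alt, ref),
        read_ratio=read_ratio(alt, ref),
        qual=rec.qual,
        gq=rec.gq,
        cipos_width=rec.end1.ci_width,
        ciend_width=rec.end2.ci_width,
        log_length=(
            math.log10(rec.length) if rec.length is not None and rec.length > 0 else None
        ),
        n_callers=n_callers,
        **{f"b1_{k}": v for k, v in ctx["b1"].items()},
        **{f"b2_{k}": v for k, v in ctx["b2"].items()},
    )
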