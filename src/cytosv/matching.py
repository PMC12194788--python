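"""Interval/breakpoint matching primitives and multi-caller consolidation.

Two SV calls (or a call and a database entry) are equivalent when:

* interval types (DEL/DUP/INV): same type and reciprocal overlap —
  ``min(|a ∩ b| / |a|, |a ∩ b| / |b|)`` — at or above a fraction (default 0.9);
* translocations: same chromosome pair and both breakend distances at or
  below a cutoff (default 1000 bp), after canonical breakend ordering.

Consolidation across callers is single-linkage clustering under this
equivalence; each cluster is represented by its highest-quality member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from intervaltree import IntervalTree

from cytosv.records import Breakend, DatabaseEntry, SVRecord


@dataclass(frozen=True)
class MatchCriteria:
    """Equivalence thresholds for SV matching."""

    overlap_frac: float = 0.9
    bnd_dist: int = 1000
    require_same_type: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_frac <= 1.0):
            raise ValueError(f"overlap_frac must be in (0,1], got {self.overlap_frac}")
        if self.bnd_dist < 0:
            raise ValueError(f"bnd_dist must be >= 0, got {self.bnd_dist}")


@dataclass(frozen=True)
class ConsolidatedSV:
    """A cluster of matching calls across callers."""

    representative: SVRecord
    callers: frozenset[str]
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.callers) < 1:
            raise ValueError("a consolidated SV needs at least one caller")
        if self.representative.id not in self.member_ids:
            raise ValueError("representative must be drawn from the members")

    @property
    def id(self) -> str:
        return self.representative.id

    @property
    def svtype(self) -> str:
        return self.representative.svtype


RecordLike = Union[SVRecord, ConsolidatedSV]


def _as_record(rec: RecordLike) -> SVRecord:
    return rec.representative if isinstance(rec, ConsolidatedSV) else rec


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap fraction of two 1-based inclusive intervals.

    Both intervals must lie on the same chromosome (the caller's concern);
    returns 0.0 when disjoint. A degenerate interval (end < start) raises.
    """
    (a0, a1), (b0, b1) = a, b
    if a1 < a0 or b1 < b0:
        raise ValueError(f"degenerate interval: {a} vs {b}")
    inter = min(a1, b1) - max(a0, b0) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0 + 1), inter / (b1 - b0 + 1))


def _entry_breakends(
    x: Union[SVRecord, DatabaseEntry]
) -> tuple[str, tuple[str, int], tuple[str, int]]:
    """(svtype, (chrom,pos), (chrom,pos)) in canonical order; svtype may be None."""
    if isinstance(x, DatabaseEntry):
        return x.svtype, (x.chrom1, x.pos1), (x.chrom2, x.pos2)
    return x.svtype, x.end1.sort_key(), x.end2.sort_key()


def svs_match(
    a: RecordLike,
    b: Union[SVRecord, DatabaseEntry, ConsolidatedSV],
    criteria: MatchCriteria = MatchCriteria(),
) -> bool:
    """Decide whether an SV call matches another call or a database entry."""
    a = _as_record(a)
    if isinstance(b, ConsolidatedSV):
        b = b.representative
    btype, b1, b2 = _entry_breakends(b)
    if a.svtype == "TRS":
        if btype != "TRS":
            return False
        (ac1, ap1), (ac2, ap2) = a.end1.sort_key(), a.end2.sort_key()
        (bc1, bp1), (bc2, bp2) = b1, b2
        if (ac1, ac2) != (bc1, bc2):
            return False
        return abs(ap1 - bp1) <= criteria.bnd_dist and abs(ap2 - bp2) <= criteria.bnd_dist
    # interval types
    if btype == "TRS" or btype is None and criteria.require_same_type:
        return False
    if criteria.require_same_type and btype != a.svtype:
        return False
    if b1[0] != a.end1.chrom or b2[0] != a.end1.chrom:
        return False
    return (
        reciprocal_overlap((a.end1.pos, a.end2.pos), (b1[1], b2[1]))
        >= criteria.overlap_frac
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def consolidate_calls(
    per_caller: Mapping[str, Sequence[SVRecord]],
    criteria: MatchCriteria = MatchCriteria(),
) -> list[ConsolidatedSV]:
    """Merge matching calls across callers by single-linkage clustering.

    The cluster representative is the member with the highest ``qual`` (ties
    broken toward the lexicographically smallest id); output is sorted by the
    representative's first breakend.
    """
    records = [rec for caller in sorted(per_caller) for rec in per_caller[caller]]
    # cluster within buckets that can possibly match, to avoid all-pairs
    buckets: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        if rec.svtype == "TRS":
            key = ("TRS", rec.end1.chrom, rec.end2.chrom)
        else:
            key = (rec.svtype, rec.end1.chrom)
        buckets.setdefault(key, []).append(i)

    uf = _UnionFind(len(records))
    for idxs in buckets.values():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1:]:
                if svs_match(records[i], records[j], criteria):
                    uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(records)):
        clusters.setdefault(uf.find(i), []).append(i)

    out = []
    for members in clusters.values():
        recs = [records[i] for i in members]
        rep = min(recs, key=lambda r: (-r.qual, r.id))
        callers = frozenset().union(*(r.callers for r in recs))
        out.append(
            ConsolidatedSV(
                representative=rep,
                callers=callers,
                member_ids=tuple(sorted(r.id for r in recs)),
            )
        )
    out.sort(key=lambda c: (c.representative.end1.chrom, c.representative.end1.pos, c.id))
    return out


class DatabaseIndex:
    """Chromosome-indexed database entries for fast candidate lookup."""

    def __init__(self, entries: Iterable[DatabaseEntry]) -> None:
        self.interval_trees: dict[str, IntervalTree] = {}
        self.bnd_buckets: dict[tuple[str, str], list[DatabaseEntry]] = {}
        for e in entries:
            if e.svtype == "TRS":
                self.bnd_buckets.setdefault((e.chrom1, e.chrom2), []).append(e)
            else:
                tree = self.interval_trees.setdefault(e.chrom1, IntervalTree())
                # intervaltree is half-open; widen the end by one base
                tree.addi(e.pos1, e.pos2 + 1, e)

    def candidates(self, rec: SVRecord, bnd_dist: int) -> list[DatabaseEntry]:
        if rec.svtype == "TRS":
            bucket = self.bnd_buckets.get((rec.end1.chrom, rec.end2.chrom), [])
            return [
                e
                for e in bucket
                if abs(e.pos1 - rec.end1.pos) <= bnd_dist
                and abs(e.pos2 - rec.end2.pos) <= bnd_dist
            ]
        tree = self.interval_trees.get(rec.end1.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(rec.end1.pos, rec.end2.pos + 1)]


def annotate_against_database(
    records: Iterable[RecordLike],
    entries: Sequence[DatabaseEntry],
    criteria: MatchCriteria = MatchCriteria(),
) -> dict[str, set[tuple]]:
    """Match every record against a database; equivalent to all-pairs testing.

    Returns, per record id, the set of ``(source, entry_id, qc_flags, af)``
    tuples of entries that match under :func:`svs_match`.
    """
    index = DatabaseIndex(entries)
    out: dict[str, set[tuple]] = {}
    for rec in records:
        r = _as_record(rec)
        hits = {
            (e.source, e.entry_id, e.qc_flags, e.af)
            for e in index.candidates(r, criteria.bnd_dist)
            if svs_match(r, e, criteria)
        }
        out[r.id] = hits
    return out
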