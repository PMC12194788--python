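"""Truth-class assignment: artifact (-1), germline (1), somatic (2).

The rules form a strict precedence ladder, which is the only reading under
which the three class definitions are disjoint:

1. **artifact** — matched to a germline-panel entry carrying an artifact
   quality flag, OR carried by a high fraction of control donors, OR either
   breakend inside a centromere;
2. else **germline** — matched to any germline resource entry whose quality
   flags are PASS-only;
3. else **somatic** — matched to a somatic-hotspot entry with no germline
   match of any kind and a donor fraction below threshold;
4. else **unlabeled**.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from cytosv.matching import (
    ConsolidatedSV,
    MatchCriteria,
    RecordLike,
    _as_record,
    svs_match,
)
from cytosv.records import DatabaseEntry, SVRecord

ARTIFACT = -1
GERMLINE = 1
SOMATIC = 2
UNLABELED = None

DEFAULT_ARTIFACT_FLAGS = frozenset(
    {"PCRPLUS_ENRICHED", "VARIABLE_ACROSS_BATCHES", "PREDICTED_GENOTYPING_ARTIFACT"}
)

GERMLINE_SOURCES = ("germline_panel", "germline_phase3")
SOMATIC_SOURCES = ("somatic_hotspot_A", "somatic_hotspot_B")


@dataclass
class LabelContext:
    """Configuration for the labeling rules.

    ``donor_af_threshold`` is the carrier fraction in the control-donor
    cohort at or above which a call is treated as a technical artifact;
    1% is the conventional cutoff for a common variant.
    """

    artifact_flags: frozenset[str] = DEFAULT_ARTIFACT_FLAGS
    donor_af_threshold: float = 0.01
    centromeres: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.donor_af_threshold <= 1.0):
            raise ValueError(
                f"donor_af_threshold must be in (0,1], got {self.donor_af_threshold}"
            )

    @classmethod
    def from_centromere_entries(
        cls, entries: Iterable[DatabaseEntry], **kwargs
    ) -> "LabelContext":
        cen: dict[str, list[tuple[int, int]]] = {}
        for e in entries:
            cen.setdefault(e.chrom1, []).append((e.pos1, e.pos2))
        return cls(centromeres=cen, **kwargs)


@dataclass(frozen=True)
class LabeledSV:
    """An SV with its truth class and the evidence that produced it."""

    record: RecordLike
    klass: int | None
    evidence: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.klass not in (ARTIFACT, GERMLINE, SOMATIC, UNLABELED):
            raise ValueError(f"unknown class {self.klass!r}")
        if self.klass is not UNLABELED and not self.evidence:
            raise ValueError("a labeled SV must carry evidence")
        object.__setattr__(self, "evidence", tuple(tuple(e) for e in self.evidence))

    @property
    def id(self) -> str:
        return _as_record(self.record).id

    @property
    def svtype(self) -> str:
        return _as_record(self.record).svtype


def donor_af(
    record: RecordLike,
    donor_calls: Sequence[DatabaseEntry],
    n_donors: int,
    criteria: MatchCriteria = MatchCriteria(),
) -> float:
    """Fraction of control donors carrying an SV matching ``record``.

    ``donor_calls`` is the consolidated donor call set; each entry's
    ``carriers`` count (defaulting to 1) is summed over matching entries.
    """
    if n_donors < 1:
        raise ValueError(f"n_donors must be >= 1, got {n_donors}")
    rec = _as_record(record)
    carriers = sum(
        (e.carriers if e.carriers is not None else 1)
        for e in donor_calls
        if svs_match(rec, e, criteria)
    )
    return min(carriers / n_donors, 1.0)


def _in_centromere(rec: SVRecord, ctx: LabelContext) -> str | None:
    for end in (rec.end1, rec.end2):
        for lo, hi in ctx.centromeres.get(end.chrom, ()):
            if lo <= end.pos <= hi:
                return f"{end.chrom}:{lo}-{hi}"
    return None


def label_sv(
    record: RecordLike,
    matches: set[tuple],
    ctx: LabelContext,
    donor_frac: float = 0.0,
) -> LabeledSV:
    """Assign one truth class from database matches, donor AF and centromeres.

    ``matches`` is the record's annotation set from
    :func:`~cytosv.matching.annotate_against_database`:
    ``(source, entry_id, qc_flags, af)`` tuples. Evidence lists every rule
    component that fired, so precedence decisions are auditable.
    """
    rec = _as_record(record)
    matches = sorted(matches)  # deterministic evidence order

    artifact_ev: list[tuple[str, str]] = []
    for source, entry_id, qc_flags, _af in matches:
        if source in GERMLINE_SOURCES and qc_flags & ctx.artifact_flags:
            flags = ",".join(sorted(qc_flags & ctx.artifact_flags))
            artifact_ev.append(("artifact_flag_match", f"{source}:{entry_id}[{flags}]"))
    if donor_frac >= ctx.donor_af_threshold:
        artifact_ev.append(("high_donor_af", f"donor_frac={donor_frac:.4g}"))
    cen_hit = _in_centromere(rec, ctx)
    if cen_hit is not None:
        artifact_ev.append(("centromeric", cen_hit))
    if artifact_ev:
        return LabeledSV(record=record, klass=ARTIFACT, evidence=tuple(artifact_ev))

    pass_germline = [
        (source, entry_id)
        for source, entry_id, qc_flags, _af in matches
        if source in GERMLINE_SOURCES and qc_flags == frozenset({"PASS"})
    ]
    if pass_germline:
        ev = tuple(("germline_pass_match", f"{s}:{e}") for s, e in pass_germline)
        return LabeledSV(record=record, klass=GERMLINE, evidence=ev)

    any_germline = any(s in GERMLINE_SOURCES for s, *_ in matches)
    somatic_hits = [(s, e) for s, e, *_ in matches if s in SOMATIC_SOURCES]
    if somatic_hits and not any_germline and donor_frac < ctx.donor_af_threshold:
        ev = tuple(("somatic_hotspot_match", f"{s}:{e}") for s, e in somatic_hits)
        return LabeledSV(record=record, klass=SOMATIC, evidence=ev)

    return LabeledSV(record=record, klass=UNLABELED, evidence=())


def build_truth_set(
    records: Sequence[RecordLike],
    databases: Sequence[DatabaseEntry],
    donor_calls: Sequence[DatabaseEntry],
    ctx: LabelContext,
    n_donors: int = 1,
    criteria: MatchCriteria = MatchCriteria(),
) -> tuple[list[LabeledSV], dict]:
    """Label every record and summarize class counts per SV type.

    Returns the labeled records (input order preserved) and a summary
    ``{klass: {svtype: count}}`` with klass keys ``-1``, ``1``, ``2`` and
    ``"unlabeled"``.
    """
    from cytosv.matching import annotate_against_database

    annotations = annotate_against_database(records, databases, criteria)
    labeled = []
    summary: dict = {}
    for rec in records:
        r = _as_record(rec)
        frac = donor_af(r, donor_calls, n_donors, criteria) if donor_calls else 0.0
        lab = label_sv(rec, annotations.get(r.id, set()), ctx, frac)
        labeled.append(lab)
        key = "unlabeled" if lab.klass is UNLABELED else lab.klass
        summary.setdefault(key, {})
        summary[key][r.svtype] = summary[key].get(r.svtype, 0) + 1
    return labeled, summary
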