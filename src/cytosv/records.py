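"""Domain types and IO for multi-caller SV call sets and annotation resources.

Coordinates are 1-based inclusive throughout (VCF convention). BED inputs are
converted on read. Translocations arrive as paired VCF breakend (BND) records
and are collapsed to a single ``TRS`` record whose ``end1`` is the breakend
with the lexicographically smaller ``(chrom, pos)``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SVTYPES = ("DEL", "DUP", "INV", "TRS")
INTERVAL_TYPES = ("DEL", "DUP", "INV")
GENOTYPES = ("hom_ref", "het", "hom_alt", "uncertain")

DATABASE_SOURCES = (
    "germline_panel",
    "germline_phase3",
    "somatic_hotspot_A",
    "somatic_hotspot_B",
    "donor_cohort",
    "centromere",
)

_BND_ALT_RE = re.compile(r"[\[\]](?P<chrom>[^:\[\]]+):(?P<pos>\d+)[\[\]]")


@dataclass(frozen=True)
class Breakend:
    """One end of a structural variant.

    ``ci_lo``/``ci_hi`` are signed offsets (bp) of the confidence interval
    around ``pos``; both ``None`` when the caller reported no interval.
    """

    chrom: str
    pos: int
    ci_lo: int | None = 0
    ci_hi: int | None = 0
    orientation: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if self.ci_lo is not None and self.ci_hi is not None:
            if not (self.ci_lo <= 0 <= self.ci_hi):
                raise ValueError(
                    f"confidence interval must straddle 0: ({self.ci_lo}, {self.ci_hi})"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_lo is not None and self.ci_hi is not None

    @property
    def ci_width(self) -> int | None:
        if not self.has_ci:
            return None
        return self.ci_hi - self.ci_lo

    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class SVRecord:
    """A consolidated SV call with genotype and read support.

    ``ref_reads``/``alt_reads`` hold one count per breakend; callers that
    report a single pair per record contribute the same counts to both ends.
    """

    id: str
    svtype: str
    end1: Breakend
    end2: Breakend
    length: int | None = None
    callers: frozenset[str] = field(default_factory=frozenset)
    genotype: str = "uncertain"
    gq: float = 0.0
    ref_reads: tuple[int, int] = (0, 0)
    alt_reads: tuple[int, int] = (0, 0)
    qual: float = 0.0

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.svtype == "TRS":
            if self.end1.chrom == self.end2.chrom:
                raise ValueError("TRS breakends must lie on different chromosomes")
            if self.length is not None:
                raise ValueError("TRS records carry no length")
        else:
            if self.end1.chrom != self.end2.chrom:
                raise ValueError(f"{self.svtype} breakends must share a chromosome")
            expected = self.end2.pos - self.end1.pos
            if expected < 0:
                raise ValueError("end2 must not precede end1")
            if self.length is not None and self.length != expected:
                raise ValueError(
                    f"length {self.length} != end2.pos - end1.pos = {expected}"
                )
        for counts in (self.ref_reads, self.alt_reads):
            if any(c < 0 for c in counts):
                raise ValueError("read counts must be non-negative")

    @property
    def interval(self) -> tuple[int, int] | None:
        """1-based inclusive span for interval types; None for TRS."""
        if self.svtype == "TRS":
            return None
        return (self.end1.pos, self.end2.pos)


@dataclass(frozen=True)
class DatabaseEntry:
    """One record from an annotation resource.

    Interval entries use ``chrom1 == chrom2`` with ``pos1..pos2`` as the span;
    breakend-pair entries (translocations) use the two ``(chrom, pos)`` pairs.
    Centromere entries are plain intervals with ``svtype`` of ``None``.
    ``carriers`` is the number of cohort members carrying the variant
    (donor-cohort resources only).
    """

    source: str
    entry_id: str
    svtype: str | None
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    qc_flags: frozenset[str] = frozenset()
    af: float | None = None
    carriers: int | None = None

    def __post_init__(self) -> None:
        if self.source not in DATABASE_SOURCES:
            raise ValueError(f"unknown database source {self.source!r}")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele frequency out of [0,1]: {self.af}")
        if self.source == "centromere" and self.svtype is not None:
            raise ValueError("centromere entries carry no svtype")

    @property
    def is_breakend_pair(self) -> bool:
        return self.svtype == "TRS"

    @property
    def interval(self) -> tuple[int, int] | None:
        if self.is_breakend_pair:
            return None
        return (self.pos1, self.pos2)


def _canonical_pair(a: Breakend, b: Breakend) -> tuple[Breakend, Breakend]:
    return (a, b) if a.sort_key() <= b.sort_key() else (b, a)


def _map_genotype(alleles: Sequence[int]) -> str:
    # cyvcf2 encodes missing alleles as -1; half-missing is also uncertain
    if len(alleles) < 2 or any(a < 0 for a in alleles):
        return "uncertain"
    a, b = alleles[0], alleles[1]
    if a == 0 and b == 0:
        return "hom_ref"
    if a > 0 and b > 0:
        return "hom_alt"
    return "het"


def _sample_index(vcf: VCF, sample: str | None) -> int:
    if not vcf.samples:
        raise ValueError("VCF carries no sample columns")
    if sample is None:
        return 0
    try:
        return vcf.samples.index(sample)
    except ValueError:
        raise ValueError(f"sample {sample!r} absent from VCF (has {vcf.samples})")


def _format_count(variant, idx: int, *names: str) -> int | None:
    for name in names:
        arr = variant.format(name)
        if arr is not None:
            v = arr[idx]
            try:
                v = v[0]
            except (TypeError, IndexError):
                pass
            v = int(v)
            return max(v, 0) if v >= 0 else None
    return None


def _ci_pair(variant, key: str) -> tuple[int | None, int | None]:
    ci = variant.INFO.get(key)
    if ci is None:
        return (None, None)
    if isinstance(ci, (int, float)):
        ci = (int(ci), int(ci))
    lo, hi = int(ci[0]), int(ci[1])
    return (min(lo, 0), max(hi, 0))


def read_caller_vcf(
    path: str | Path,
    caller: str,
    sample: str | None = None,
    report: dict | None = None,
) -> list[SVRecord]:
    """Read one caller's VCF into :class:`SVRecord` objects.

    Symbolic ``<DEL>/<DUP>/<INV>`` records require INFO ``END``; paired BND
    records (matched via ``MATEID`` or by reciprocal coordinates) collapse to
    one ``TRS`` record each. Malformed records are skipped and counted in
    ``report``; BND records whose mate cannot be located are dropped with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such VCF: {path}")
    if report is None:
        report = {}
    report.setdefault("skipped_malformed", 0)
    report.setdefault("unpaired_bnd", 0)

    vcf = VCF(str(path))
    idx = _sample_index(vcf, sample)

    records: list[SVRecord] = []
    # id -> (breakend, mate_chrom, mate_pos, mateid, shared fields)
    bnd_pool: dict[str, dict] = {}

    for variant in vcf:
        svtype = variant.INFO.get("SVTYPE")
        alt = variant.ALT[0] if variant.ALT else None
        if svtype is None and alt is not None and alt.startswith("<"):
            svtype = alt.strip("<>")
        if svtype is None and alt is not None and ("[" in alt or "]" in alt):
            svtype = "BND"
        if svtype not in ("DEL", "DUP", "INV", "BND"):
            report["skipped_malformed"] += 1
            continue

        genotype = _map_genotype(variant.genotypes[idx][:2])
        gq_arr = variant.gt_quals
        gq = float(gq_arr[idx]) if gq_arr is not None and gq_arr[idx] >= 0 else 0.0
        ref = _format_count(variant, idx, "RO", "DR")
        altc = _format_count(variant, idx, "AO", "DV")
        ref = 0 if ref is None else ref
        altc = 0 if altc is None else altc
        qual = float(variant.QUAL) if variant.QUAL is not None else 0.0
        ci_lo, ci_hi = _ci_pair(variant, "CIPOS")
        vid = variant.ID or f"{variant.CHROM}_{variant.POS}"

        if svtype == "BND":
            m = _BND_ALT_RE.search(alt or "")
            if m is None:
                report["skipped_malformed"] += 1
                continue
            orientation = "+" if "[" in alt else "-"
            bnd_pool[vid] = {
                "end": Breakend(variant.CHROM, variant.POS, ci_lo, ci_hi, orientation),
                "mate_chrom": m.group("chrom"),
                "mate_pos": int(m.group("pos")),
                "mateid": variant.INFO.get("MATEID"),
                "genotype": genotype,
                "gq": gq,
                "ref": ref,
                "alt": altc,
                "qual": qual,
            }
            continue

        end_pos = variant.INFO.get("END")
        if end_pos is None:
            report["skipped_malformed"] += 1
            continue
        end_pos = int(end_pos)
        ce_lo, ce_hi = _ci_pair(variant, "CIEND")
        end1 = Breakend(variant.CHROM, variant.POS, ci_lo, ci_hi)
        end2 = Breakend(variant.CHROM, end_pos, ce_lo, ce_hi)
        if end2.pos < end1.pos:
            end1, end2 = (
                Breakend(variant.CHROM, end_pos, ce_lo, ce_hi),
                Breakend(variant.CHROM, variant.POS, ci_lo, ci_hi),
            )
        records.append(
            SVRecord(
                id=f"{caller}:{vid}",
                svtype=svtype,
                end1=end1,
                end2=end2,
                length=end2.pos - end1.pos,
                callers=frozenset({caller}),
                genotype=genotype,
                gq=gq,
                ref_reads=(ref, ref),
                alt_reads=(altc, altc),
                qual=qual,
            )
        )

    records.extend(_pair_bnds(bnd_pool, caller, report))
    records.sort(key=lambda r: (r.end1.chrom, r.end1.pos, r.id))
    return records


def _pair_bnds(pool: dict[str, dict], caller: str, report: dict) -> list[SVRecord]:
    """Collapse mated BND records into TRS records (one per pair)."""
    out: list[SVRecord] = []
    done: set[str] = set()
    # fallback index for records without MATEID: locate mate by coordinates
    coord_index: dict[tuple[str, int, str, int], list[str]] = {}
    for vid, b in pool.items():
        key = (b["end"].chrom, b["end"].pos, b["mate_chrom"], b["mate_pos"])
        coord_index.setdefault(key, []).append(vid)

    for vid in sorted(pool):
        if vid in done:
            continue
        b = pool[vid]
        mate_id = b["mateid"]
        if mate_id is not None and mate_id not in pool:
            mate_id = None
        if mate_id is None:
            rkey = (b["mate_chrom"], b["mate_pos"], b["end"].chrom, b["end"].pos)
            candidates = [m for m in coord_index.get(rkey, []) if m not in done and m != vid]
            mate_id = candidates[0] if candidates else None
        if mate_id is None or mate_id in done:
            logger.warning("BND %s:%s has no locatable mate; dropped", caller, vid)
            report["unpaired_bnd"] += 1
            done.add(vid)
            continue
        m = pool[mate_id]
        done.update({vid, mate_id})
        if b["end"].chrom == m["end"].chrom:
            # intra-chromosomal breakend pair: not a translocation in this model
            report["skipped_malformed"] += 1
            continue
        e1, e2 = _canonical_pair(b["end"], m["end"])
        first = b if e1 == b["end"] else m
        second = m if first is b else b
        out.append(
            SVRecord(
                id=f"{caller}:{min(vid, mate_id)}",
                svtype="TRS",
                end1=e1,
                end2=e2,
                length=None,
                callers=frozenset({caller}),
                genotype=first["genotype"],
                gq=first["gq"],
                ref_reads=(first["ref"], second["ref"]),
                alt_reads=(first["alt"], second["alt"]),
                qual=max(first["qual"], second["qual"]),
            )
        )
    return out


def read_database(path: str | Path, source: str) -> list[DatabaseEntry]:
    """Read an annotation resource (VCF, hotspot TSV, or centromere BED).

    ``qc_flags`` come from the FILTER column (semicolon-split; an empty or
    missing FILTER reads as PASS) and ``af`` from an AF-like INFO field.
    """
    if source not in DATABASE_SOURCES:
        raise ValueError(f"unknown database source {source!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such database file: {path}")
    if source == "centromere":
        return _read_centromere_bed(path)
    if source.startswith("somatic_hotspot"):
        return _read_hotspot_tsv(path, source)
    return _read_database_vcf(path, source)


def _read_centromere_bed(path: Path) -> list[DatabaseEntry]:
    entries = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            entries.append(
                DatabaseEntry(
                    source="centromere",
                    entry_id=f"cen_{i}",
                    svtype=None,
                    chrom1=chrom,
                    pos1=start + 1,  # BED 0-based half-open -> 1-based inclusive
                    chrom2=chrom,
                    pos2=end,
                )
            )
    return entries


def _read_hotspot_tsv(path: Path, source: str) -> list[DatabaseEntry]:
    entries = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom1", "pos1", "chrom2", "pos2", "svtype", "name"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"hotspot table {path} must have columns {sorted(required)}")
        for row in reader:
            entries.append(
                DatabaseEntry(
                    source=source,
                    entry_id=row["name"],
                    svtype=row["svtype"],
                    chrom1=row["chrom1"],
                    pos1=int(row["pos1"]),
                    chrom2=row["chrom2"],
                    pos2=int(row["pos2"]),
                )
            )
    return entries


def _read_database_vcf(path: Path, source: str) -> list[DatabaseEntry]:
    vcf = VCF(str(path))
    entries: list[DatabaseEntry] = []
    bnd_pool: dict[str, dict] = {}
    for i, variant in enumerate(vcf):
        raw_filter = variant.FILTER  # None means PASS in cyvcf2
        flags = frozenset((raw_filter or "PASS").split(";"))
        af = variant.INFO.get("AF")
        if af is not None:
            try:
                af = float(af[0]) if isinstance(af, tuple) else float(af)
            except (TypeError, ValueError):
                af = None
        carriers = variant.INFO.get("CARRIERS")
        carriers = int(carriers) if carriers is not None else None
        vid = variant.ID or f"{source}_{i}"
        svtype = variant.INFO.get("SVTYPE")
        alt = variant.ALT[0] if variant.ALT else ""
        if svtype == "BND" or ("[" in alt or "]" in alt):
            m = _BND_ALT_RE.search(alt)
            if m is None:
                continue
            bnd_pool[vid] = {
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "mate_chrom": m.group("chrom"),
                "mate_pos": int(m.group("pos")),
                "mateid": variant.INFO.get("MATEID"),
                "flags": flags,
                "af": af,
                "carriers": carriers,
            }
            continue
        end_pos = variant.INFO.get("END")
        if svtype not in INTERVAL_TYPES or end_pos is None:
            continue
        entries.append(
            DatabaseEntry(
                source=source,
                entry_id=vid,
                svtype=svtype,
                chrom1=variant.CHROM,
                pos1=variant.POS,
                chrom2=variant.CHROM,
                pos2=int(end_pos),
                qc_flags=flags,
                af=af,
                carriers=carriers,
            )
        )
    entries.extend(_pair_database_bnds(bnd_pool, source))
    return entries


def _pair_database_bnds(pool: dict[str, dict], source: str) -> list[DatabaseEntry]:
    out = []
    done: set[str] = set()
    for vid in sorted(pool):
        if vid in done:
            continue
        b = pool[vid]
        mate_id = b["mateid"]
        if mate_id is None or mate_id not in pool:
            # fall back to coordinate matching
            mate_id = next(
                (
                    m
                    for m, d in pool.items()
                    if m != vid
                    and m not in done
                    and d["chrom"] == b["mate_chrom"]
                    and d["pos"] == b["mate_pos"]
                    and d["mate_chrom"] == b["chrom"]
                    and d["mate_pos"] == b["pos"]
                ),
                None,
            )
        if mate_id is None or mate_id in done:
            done.add(vid)
            continue
        done.update({vid, mate_id})
        if b["chrom"] == b["mate_chrom"]:
            continue
        (c1, p1), (c2, p2) = sorted(
            [(b["chrom"], b["pos"]), (b["mate_chrom"], b["mate_pos"])]
        )
        out.append(
            DatabaseEntry(
                source=source,
                entry_id=min(vid, mate_id),
                svtype="TRS",
                chrom1=c1,
                pos1=p1,
                chrom2=c2,
                pos2=p2,
                qc_flags=b["flags"],
                af=b["af"],
                carriers=b["carriers"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tab-delimited SV tables (round-trippable)

SV_TABLE_COLUMNS = [
    "id", "svtype",
    "chrom1", "pos1", "ci1_lo", "ci1_hi", "orient1",
    "chrom2", "pos2", "ci2_lo", "ci2_hi", "orient2",
    "length", "callers", "genotype", "gq",
    "ref_reads1", "alt_reads1", "ref_reads2", "alt_reads2",
    "qual", "klass", "evidence",
]


def _record_row(rec) -> dict:
    from cytosv.labeling import LabeledSV  # local import to avoid a cycle

    klass, evidence = "", ""
    if isinstance(rec, LabeledSV):
        klass = "unlabeled" if rec.klass is None else str(rec.klass)
        evidence = ";".join(f"{rule}|{src}" for rule, src in rec.evidence)
        rec = rec.record
    if hasattr(rec, "representative"):  # ConsolidatedSV
        rec = rec.representative
    return {
        "id": rec.id,
        "svtype": rec.svtype,
        "chrom1": rec.end1.chrom,
        "pos1": rec.end1.pos,
        "ci1_lo": "" if rec.end1.ci_lo is None else rec.end1.ci_lo,
        "ci1_hi": "" if rec.end1.ci_hi is None else rec.end1.ci_hi,
        "orient1": rec.end1.orientation or "",
        "chrom2": rec.end2.chrom,
        "pos2": rec.end2.pos,
        "ci2_lo": "" if rec.end2.ci_lo is None else rec.end2.ci_lo,
        "ci2_hi": "" if rec.end2.ci_hi is None else rec.end2.ci_hi,
        "orient2": rec.end2.orientation or "",
        "length": "" if rec.length is None else rec.length,
        "callers": ",".join(sorted(rec.callers)),
        "genotype": rec.genotype,
        "gq": repr(float(rec.gq)),
        "ref_reads1": rec.ref_reads[0],
        "alt_reads1": rec.alt_reads[0],
        "ref_reads2": rec.ref_reads[1],
        "alt_reads2": rec.alt_reads[1],
        "qual": repr(float(rec.qual)),
        "klass": klass,
        "evidence": evidence,
    }


def write_sv_table(records: Iterable, path: str | Path) -> None:
    """Write records (plain or labeled) to a stable-column TSV.

    Absent values (e.g. a TRS length) are written as empty cells, never 0.
    """
    rows = [_record_row(r) for r in records]
    df = pd.DataFrame(rows, columns=SV_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def _opt_int(v: str) -> int | None:
    return None if v == "" else int(v)


def read_sv_table(path: str | Path):
    """Read a TSV written by :func:`write_sv_table` back into records.

    Rows with a ``klass`` cell become :class:`~cytosv.labeling.LabeledSV`.
    """
    from cytosv.labeling import LabeledSV

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        rec = SVRecord(
            id=row["id"],
            svtype=row["svtype"],
            end1=Breakend(
                row["chrom1"], int(row["pos1"]),
                _opt_int(row["ci1_lo"]), _opt_int(row["ci1_hi"]),
                row["orient1"] or None,
            ),
            end2=Breakend(
                row["chrom2"], int(row["pos2"]),
                _opt_int(row["ci2_lo"]), _opt_int(row["ci2_hi"]),
                row["orient2"] or None,
            ),
            length=_opt_int(row["length"]),
            callers=frozenset(row["callers"].split(",")) if row["callers"] else frozenset(),
            genotype=row["genotype"],
            gq=float(row["gq"]),
            ref_reads=(int(row["ref_reads1"]), int(row["ref_reads2"])),
            alt_reads=(int(row["alt_reads1"]), int(row["alt_reads2"])),
            qual=float(row["qual"]),
        )
        if row["klass"] != "":
            evidence = [
                tuple(item.split("|", 1))
                for item in row["evidence"].split(";")
                if item
            ]
            klass = None if row["klass"] == "unlabeled" else int(row["klass"])
            out.append(LabeledSV(record=rec, klass=klass, evidence=evidence))
        else:
            out.append(rec)
    return out
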