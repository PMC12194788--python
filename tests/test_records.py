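import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytosv.records import (
    Breakend,
    SVRecord,
    read_caller_vcf,
    read_database,
    read_sv_table,
    write_sv_table,
)
from tests.conftest import random_sv_record

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000000>
##contig=<ID=chr2,length=10000000>
##FILTER=<ID=PCRPLUS_ENRICHED,Description="x">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="x">
##INFO=<ID=CIEND,Number=2,Type=Integer,Description="x">
##INFO=<ID=MATEID,Number=1,Type=String,Description="x">
##INFO=<ID=AF,Number=A,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=AO,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""

DEL_LINE = (
    "chr1\t{pos}\t{vid}\tN\t<DEL>\t60.0\tPASS\t"
    "SVTYPE=DEL;END={end};CIPOS=-10,10;CIEND=-20,20\tGT:GQ:RO:AO\t0/1:55:20:18\n"
)


def bnd_pair(vid, c1, p1, c2, p2):
    a = (
        f"{c1}\t{p1}\t{vid}.a\tN\tN[{c2}:{p2}[\t70.0\tPASS\t"
        f"SVTYPE=BND;MATEID={vid}.b;CIPOS=-5,5\tGT:GQ:RO:AO\t0/1:60:15:12\n"
    )
    b = (
        f"{c2}\t{p2}\t{vid}.b\tN\tN]{c1}:{p1}]\t70.0\tPASS\t"
        f"SVTYPE=BND;MATEID={vid}.a;CIPOS=-5,5\tGT:GQ:RO:AO\t0/1:60:15:12\n"
    )
    return a, b


def write_vcf(path, body):
    path.write_text(HEADER + body)
    return path


class TestReadCallerVcf:
    def test_header_only_gives_empty_sequence(self, tmp_path):
        path = write_vcf(tmp_path / "empty.vcf", "")
        assert read_caller_vcf(path, "delly") == []

    def test_two_dels_and_one_bnd_pair_give_three_records(self, tmp_path):
        a, b = bnd_pair("tr1", "chr1", 5_000_000, "chr2", 7_000_000)
        body = DEL_LINE.format(pos=1000, vid="d1", end=151_000)
        body += DEL_LINE.format(pos=300_000, vid="d2", end=600_000)
        body += a + b
        recs = read_caller_vcf(write_vcf(tmp_path / "c.vcf", body), "delly")
        assert len(recs) == 3
        assert sorted(r.svtype for r in recs) == ["DEL", "DEL", "TRS"]
        trs = next(r for r in recs if r.svtype == "TRS")
        assert (trs.end1.chrom, trs.end1.pos) == ("chr1", 5_000_000)
        assert (trs.end2.chrom, trs.end2.pos) == ("chr2", 7_000_000)
        assert trs.end1.ci_lo == -5 and trs.end1.ci_hi == 5

    def test_bnd_without_locatable_mate_is_dropped_with_warning(self, tmp_path):
        a, _ = bnd_pair("tr1", "chr1", 5_000_000, "chr2", 7_000_000)
        report = {}
        recs = read_caller_vcf(
            write_vcf(tmp_path / "c.vcf", a), "delly", report=report
        )
        assert [r for r in recs if r.svtype == "TRS"] == []
        assert report["unpaired_bnd"] == 1

    def test_bnd_pairing_is_order_invariant(self, tmp_path):
        a, b = bnd_pair("tr1", "chr1", 5_000_000, "chr2", 7_000_000)
        r1 = read_caller_vcf(write_vcf(tmp_path / "ab.vcf", a + b), "delly")
        r2 = read_caller_vcf(write_vcf(tmp_path / "ba.vcf", b + a), "delly")
        assert r1 == r2

    def test_ids_are_caller_qualified_and_genotype_mapped(self, tmp_path):
        body = DEL_LINE.format(pos=1000, vid="d1", end=151_000)
        (rec,) = read_caller_vcf(write_vcf(tmp_path / "c.vcf", body), "manta")
        assert rec.id == "manta:d1"
        assert rec.genotype == "het"
        assert rec.ref_reads == (20, 20) and rec.alt_reads == (18, 18)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_caller_vcf(tmp_path / "nope.vcf", "delly")


class TestReadDatabase:
    def test_centromere_bed_maps_to_one_based_interval(self, tmp_path):
        bed = tmp_path / "cen.bed"
        bed.write_text("chr1\t121700000\t125100000\n")
        (entry,) = read_database(bed, "centromere")
        assert entry.svtype is None
        assert (entry.pos1, entry.pos2) == (121700001, 125100000)

    def test_filter_column_is_semicolon_split_into_flags(self, tmp_path):
        body = (
            "chr1\t1000\tg1\tN\t<DEL>\t.\tPASS;PCRPLUS_ENRICHED\t"
            "SVTYPE=DEL;END=200000;AF=0.12\n"
        )
        (entry,) = read_database(write_vcf(tmp_path / "g.vcf", body), "germline_panel")
        assert entry.qc_flags == frozenset({"PASS", "PCRPLUS_ENRICHED"})
        assert entry.af == pytest.approx(0.12)

    def test_hotspot_tsv_row_count(self, tmp_path):
        tsv = tmp_path / "hot.tsv"
        lines = ["chrom1\tpos1\tchrom2\tpos2\tsvtype\tname"]
        for i in range(5):
            lines.append(f"chr1\t{1000 + i}\tchr2\t{2000 + i}\tTRS\th{i}")
        tsv.write_text("\n".join(lines) + "\n")
        entries = read_database(tsv, "somatic_hotspot_A")
        assert len(entries) == 5
        assert all(e.svtype == "TRS" for e in entries)

    def test_unknown_source_is_a_configuration_error(self, tmp_path):
        with pytest.raises(ValueError, match="unknown database source"):
            read_database(tmp_path / "x.bed", "mystery_db")


class TestSvTable:
    def test_empty_sequence_gives_header_only_file(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_sv_table([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("id\t")

    def test_trs_length_is_empty_cell_not_zero(self, tmp_path):
        rec = SVRecord(
            id="t1", svtype="TRS",
            end1=Breakend("chr1", 100), end2=Breakend("chr2", 200),
        )
        path = tmp_path / "t.tsv"
        write_sv_table([rec], path)
        header, row = path.read_text().splitlines()
        length_cell = row.split("\t")[header.split("\t").index("length")]
        assert length_cell == ""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(0, 12))
    def test_round_trip_is_identity(self, tmp_path_factory, seed, n):
        rng = random.Random(seed)
        records = [random_sv_record(rng, i) for i in range(n)]
        path = tmp_path_factory.mktemp("rt") / "t.tsv"
        write_sv_table(records, path)
        assert read_sv_table(path) == records

    def test_labeled_records_round_trip(self, tmp_path):
        from cytosv.labeling import LabeledSV

        rng = random.Random(5)
        labeled = [
            LabeledSV(random_sv_record(rng, 0), 2, (("somatic_hotspot_match", "a:b"),)),
            LabeledSV(random_sv_record(rng, 1), None),
        ]
        path = tmp_path / "t.tsv"
        write_sv_table(labeled, path)
        back = read_sv_table(path)
        assert [b.klass for b in back] == [2, None]
        assert back[0].evidence == labeled[0].evidence
        assert [b.record for b in back] == [l.record for l in labeled]
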