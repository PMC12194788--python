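import itertools
import random

import pytest

from cytosv.labeling import (
    ARTIFACT,
    GERMLINE,
    SOMATIC,
    UNLABELED,
    LabelContext,
    LabeledSV,
    donor_af,
    label_sv,
)
from cytosv.matching import MatchCriteria, svs_match
from cytosv.records import Breakend, DatabaseEntry, SVRecord
from tests.conftest import random_db_entry, random_sv_record


def make_rec(c1="chr1", p1=1_000_000, p2=2_000_000):
    return SVRecord(
        id="r1", svtype="DEL",
        end1=Breakend(c1, p1, -10, 10), end2=Breakend(c1, p2, -10, 10),
        length=p2 - p1, genotype="het", alt_reads=(5, 5), ref_reads=(5, 5),
    )


FLAG_MATCH = ("germline_panel", "gA", frozenset({"PREDICTED_GENOTYPING_ARTIFACT"}), None)
PASS_MATCH = ("germline_phase3", "gP", frozenset({"PASS"}), 0.02)
SOMATIC_MATCH = ("somatic_hotspot_A", "hS", frozenset(), None)


def expected_class(flag, pas, som, donor, cen):
    """Hand-derived precedence table for the four predicates x centromere."""
    if flag or donor or cen:
        return ARTIFACT
    if pas:
        return GERMLINE
    if som:  # no germline match of any kind survives to this branch
        return SOMATIC
    return UNLABELED


class TestDonorAf:
    def test_carrier_fraction(self):
        rec = make_rec()
        donor = DatabaseEntry(
            source="donor_cohort", entry_id="d", svtype="DEL",
            chrom1="chr1", pos1=1_000_000, chrom2="chr1", pos2=2_000_000,
            carriers=3,
        )
        assert donor_af(rec, [donor], 100) == pytest.approx(0.03)
        assert donor_af(rec, [], 100) == 0.0

    def test_zero_donors_is_a_domain_error(self):
        with pytest.raises(ValueError):
            donor_af(make_rec(), [], 0)

    def test_matches_brute_force_carrier_count(self):
        rng = random.Random(42)
        records = [random_sv_record(rng, i) for i in range(60)]
        donors = [random_db_entry(rng, i) for i in range(60)]
        donors = [d for d in donors if d.source == "donor_cohort"]
        crit = MatchCriteria()
        for rec in records:
            expected = sum(
                (d.carriers or 1) for d in donors if svs_match(rec, d, crit)
            ) / 100
            assert donor_af(rec, donors, 100) == pytest.approx(min(expected, 1.0))


class TestLabelPrecedence:
    @pytest.mark.parametrize(
        "flag,pas,som,donor,cen",
        list(itertools.product([False, True], repeat=5)),
    )
    def test_exhaustive_precedence(self, flag, pas, som, donor, cen):
        matches = set()
        if flag:
            matches.add(FLAG_MATCH)
        if pas:
            matches.add(PASS_MATCH)
        if som:
            matches.add(SOMATIC_MATCH)
        ctx = LabelContext(
            centromeres={"chr1": [(900_000, 1_100_000)]} if cen else {}
        )
        donor_frac = 0.5 if donor else 0.0
        lab = label_sv(make_rec(), matches, ctx, donor_frac)
        assert lab.klass == expected_class(flag, pas, som, donor, cen)
        if lab.klass is not UNLABELED:
            assert lab.evidence

    def test_artifact_flag_match_wins_over_everything(self):
        lab = label_sv(
            make_rec(), {FLAG_MATCH, PASS_MATCH, SOMATIC_MATCH}, LabelContext(), 0.0
        )
        assert lab.klass == ARTIFACT
        assert any(rule == "artifact_flag_match" for rule, _ in lab.evidence)

    def test_somatic_with_pass_germline_is_germline_not_somatic(self):
        lab = label_sv(make_rec(), {SOMATIC_MATCH, PASS_MATCH}, LabelContext(), 0.0)
        assert lab.klass == GERMLINE

    def test_pure_somatic_hotspot_labels_somatic(self):
        lab = label_sv(make_rec(), {SOMATIC_MATCH}, LabelContext(), 0.0)
        assert lab.klass == SOMATIC

    def test_non_pass_non_artifact_germline_flag_leaves_record_eligible(self):
        # e.g. LOWQUAL: neither germline nor artifact; blocks somatic though
        odd = ("germline_panel", "gX", frozenset({"LOWQUAL"}), None)
        assert label_sv(make_rec(), {odd}, LabelContext(), 0.0).klass is UNLABELED
        assert label_sv(make_rec(), {odd, SOMATIC_MATCH}, LabelContext(), 0.0).klass is UNLABELED

    def test_removing_somatic_entries_never_creates_artifacts(self):
        # monotonicity of the ladder: class 2 falls to 1 or unlabeled only
        for extra in (set(), {PASS_MATCH}):
            with_som = label_sv(make_rec(), {SOMATIC_MATCH} | extra, LabelContext(), 0.0)
            without = label_sv(make_rec(), extra, LabelContext(), 0.0)
            if with_som.klass == SOMATIC:
                assert without.klass in (GERMLINE, UNLABELED)

    def test_labels_invariant_to_match_order(self):
        matches = [FLAG_MATCH, PASS_MATCH, SOMATIC_MATCH]
        ctx = LabelContext()
        expected = label_sv(make_rec(), set(matches), ctx, 0.0)
        for perm in itertools.permutations(matches):
            lab = label_sv(make_rec(), set(perm), ctx, 0.0)
            assert lab.klass == expected.klass and lab.evidence == expected.evidence

    def test_centromere_hit_uses_breakend_positions(self):
        ctx = LabelContext(centromeres={"chr1": [(1_900_000, 2_100_000)]})
        assert label_sv(make_rec(), set(), ctx, 0.0).klass == ARTIFACT  # end2 inside
        ctx2 = LabelContext(centromeres={"chr1": [(2_500_000, 2_600_000)]})
        assert label_sv(make_rec(), set(), ctx2, 0.0).klass is UNLABELED

    def test_labeled_sv_requires_evidence(self):
        with pytest.raises(ValueError):
            LabeledSV(record=make_rec(), klass=SOMATIC, evidence=())


class TestBuildTruthSet:
    def test_empty_input_gives_empty_output(self):
        from cytosv.labeling import build_truth_set

        labeled, summary = build_truth_set([], [], [], LabelContext())
        assert labeled == [] and summary == {}

    def test_zero_jitter_cohort_recovers_planted_counts(self, zero_jitter_cohort):
        from cytosv.labeling import build_truth_set
        from cytosv.matching import consolidate_calls
        from cytosv.qc import apply_basic_qc, filter_by_length
        from cytosv.records import read_caller_vcf, read_database

        files = zero_jitter_cohort
        per_caller = {}
        for caller, path in files.caller_vcfs.items():
            report = {}
            recs = read_caller_vcf(path, caller, report=report)
            assert report == {"skipped_malformed": 0, "unpaired_bnd": 0}
            kept, _ = apply_basic_qc(recs)
            per_caller[caller] = filter_by_length(kept, 1_000_000)
        consolidated = consolidate_calls(per_caller)
        databases = (
            read_database(files.germline_panel, "germline_panel")
            + read_database(files.germline_phase3, "germline_phase3")
            + read_database(files.hotspot_a, "somatic_hotspot_A")
            + read_database(files.hotspot_b, "somatic_hotspot_B")
        )
        donors = read_database(files.donor_vcf, "donor_cohort")
        cen = read_database(files.reference.centromere_bed, "centromere")
        ctx = LabelContext.from_centromere_entries(cen)
        _, summary = build_truth_set(
            consolidated, databases, donors, ctx, n_donors=files.config.n_donors
        )
        assert summary == files.truth.class_counts()
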