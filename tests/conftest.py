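import random

import pytest

from cytosv.matching import MatchCriteria
from cytosv.records import Breakend, DatabaseEntry, SVRecord
from cytosv.simulate import CohortConfig, plant_sv_cohort

CHROMS = ("chr1", "chr2", "chr3")


def random_sv_record(rng: random.Random, idx: int, svtype: str | None = None) -> SVRecord:
    if svtype is None:
        svtype = rng.choice(["DEL", "DUP", "INV", "TRS"])
    gq = round(rng.uniform(0, 99), 1)
    qual = round(rng.uniform(0, 500), 1)
    genotype = rng.choice(["hom_ref", "het", "hom_alt", "uncertain"])
    callers = frozenset(rng.sample(["delly", "manta", "breakdancer"], rng.randint(1, 3)))
    reads = lambda: (rng.randint(0, 80), rng.randint(0, 80))  # noqa: E731
    r1, r2 = reads(), reads()
    ci = lambda: (-rng.randint(0, 200), rng.randint(0, 200))  # noqa: E731
    if svtype == "TRS":
        c1, c2 = rng.sample(CHROMS, 2)
        if (c2, 1) < (c1, 1):
            c1, c2 = c2, c1
        e1 = Breakend(c1, rng.randint(1, 9_000_000), *ci(), rng.choice(["+", "-"]))
        e2 = Breakend(c2, rng.randint(1, 9_000_000), *ci(), rng.choice(["+", "-"]))
        length = None
    else:
        chrom = rng.choice(CHROMS)
        start = rng.randint(1, 8_000_000)
        length = rng.randint(1, 2_000_000)
        e1 = Breakend(chrom, start, *ci())
        e2 = Breakend(chrom, start + length, *ci())
    return SVRecord(
        id=f"r{idx:04d}",
        svtype=svtype,
        end1=e1,
        end2=e2,
        length=length,
        callers=callers,
        genotype=genotype,
        gq=gq,
        ref_reads=r1,
        alt_reads=r2,
        qual=qual,
    )


def random_db_entry(rng: random.Random, idx: int) -> DatabaseEntry:
    source = rng.choice(
        ["germline_panel", "germline_phase3", "somatic_hotspot_A", "donor_cohort"]
    )
    svtype = rng.choice(["DEL", "DUP", "INV", "TRS"])
    flags = frozenset(
        rng.sample(
            ["PASS", "PCRPLUS_ENRICHED", "VARIABLE_ACROSS_BATCHES", "LOWQUAL"],
            rng.randint(1, 2),
        )
    )
    af = round(rng.random(), 3) if rng.random() < 0.5 else None
    if svtype == "TRS":
        c1, c2 = sorted(rng.sample(CHROMS, 2))
        p1, p2 = rng.randint(1, 9_000_000), rng.randint(1, 9_000_000)
    else:
        c1 = c2 = rng.choice(CHROMS)
        p1 = rng.randint(1, 8_000_000)
        p2 = p1 + rng.randint(1, 2_000_000)
    return DatabaseEntry(
        source=source,
        entry_id=f"e{idx:04d}",
        svtype=svtype,
        chrom1=c1,
        pos1=p1,
        chrom2=c2,
        pos2=p2,
        qc_flags=flags,
        af=af,
    )


def brute_force_annotate(records, entries, criteria=MatchCriteria()):
    """All-pairs oracle for annotate_against_database."""
    from cytosv.matching import svs_match

    out = {}
    for rec in records:
        out[rec.id] = {
            (e.source, e.entry_id, e.qc_flags, e.af)
            for e in entries
            if svs_match(rec, e, criteria)
        }
    return out


SMALL = dict(
    n_chroms=3,
    chrom_len=4_000_000,
    sv_len_range=(1_100_000, 1_900_000),
    n_artifact=12,
    n_germline=16,
    n_somatic=10,
    n_decoy=5,
)


@pytest.fixture(scope="session")
def zero_jitter_cohort(tmp_path_factory):
    """Small cohort with no breakpoint jitter and full caller detection."""
    cfg = CohortConfig(seed=17, jitter=0, detection_prob=1.0, **SMALL)
    return plant_sv_cohort(cfg, tmp_path_factory.mktemp("cohort_j0"))


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The full default cohort (study conditions)."""
    cfg = CohortConfig(seed=29)
    return plant_sv_cohort(cfg, tmp_path_factory.mktemp("cohort_default"))


@pytest.fixture(scope="session")
def default_run(default_cohort, tmp_path_factory):
    """One end-to-end pipeline run on the default cohort, shared by tests."""
    from cytosv.pipeline import RunConfig, run_end_to_end

    outdir = tmp_path_factory.mktemp("run_default")
    config = RunConfig.from_cohort(default_cohort, outdir, importance_repeats=3)
    return run_end_to_end(config), outdir
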