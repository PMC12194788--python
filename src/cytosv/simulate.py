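"""Synthetic cohort generation: reference, caller VCFs, databases, truth.

Everything downstream consumes caller-level VCFs plus annotation resources,
so simulation starts there (no read-level data). The generator plants large
SVs (>= 1 Mb, the cytogenetic size regime) of known class and emits:

* a random-composition reference FASTA with recorded low-complexity tracts
  and one centromere interval per chromosome (BED);
* per-caller VCFs where each planted SV is re-called with breakpoint jitter,
  class-conditional read counts, genotype quality and confidence intervals;
* a germline panel VCF (PASS entries for germline SVs, artifact-flagged
  entries for one artifact mode), a second germline resource VCF, somatic
  hotspot tables, and a donor-cohort VCF with carrier counts;
* a truth table mapping every planted SV id to its class.

Artifact SVs draw one of three evidence modes: an artifact-flagged panel
entry, placement inside a centromere, or high donor-cohort frequency. Decoy
SVs match no resource and exercise the unlabeled path.

Class-conditional feature distributions (read ratio, genotype quality,
confidence-interval width, low-complexity breakend placement) are the
study conditions every classifier test runs under; they are set once here.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cytosv.features import FEATURE_NAMES

ARTIFACT_FLAG_CHOICES = (
    "PCRPLUS_ENRICHED",
    "VARIABLE_ACROSS_BATCHES",
    "PREDICTED_GENOTYPING_ARTIFACT",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    # genome shape: 4 x 10 Mb leaves room for many >= 1 Mb SVs
    n_chroms: int = 4
    chrom_len: int = 10_000_000
    gc: float = 0.41
    n_lowc_tracts: int = 8          # poly-A tracts per chromosome
    tract_len: int = 400
    centromere_span: tuple[float, float] = (0.40, 0.52)  # fraction of chrom

    # cohort composition, per group (TRS and non-TRS each get these counts)
    n_artifact: int = 80
    n_germline: int = 100
    n_somatic: int = 60
    n_decoy: int = 20
    nontrs_mix: dict = field(
        default_factory=lambda: {"DEL": 0.4, "DUP": 0.3, "INV": 0.3}
    )
    sv_len_range: tuple[int, int] = (1_200_000, 3_000_000)

    # labeling evidence
    n_donors: int = 100
    germline_donor_freq: float = 0.0   # see docs: must stay below the donor-AF
    #                                    artifact threshold for planted germline
    artifact_mode_probs: dict = field(
        default_factory=lambda: {"flag": 0.4, "centromere": 0.3, "donor": 0.3}
    )
    artifact_donor_freq: float = 0.20
    artifact_lowc_prob: float = 0.5
    germline_panel_prob: float = 0.7
    germline_phase3_prob: float = 0.5
    germline_af: float = 0.05

    # caller behavior
    callers: tuple[str, ...] = ("delly", "manta", "breakdancer")
    detection_prob: float = 0.85
    jitter: int = 50
    # class-conditional distributions: (read_ratio mean, sd), gq (mean, sd),
    # qual (mean, sd), CI width range
    somatic_read_ratio: tuple[float, float] = (0.30, 0.04)
    artifact_read_ratio: tuple[float, float] = (0.10, 0.03)
    germline_het_prob: float = 0.85
    gq_params: dict = field(
        default_factory=lambda: {
            "artifact": (18.0, 6.0),
            "germline": (70.0, 8.0),
            "somatic": (55.0, 8.0),
            "decoy": (40.0, 15.0),
        }
    )
    qual_params: dict = field(
        default_factory=lambda: {
            "artifact": (30.0, 10.0),
            "germline": (90.0, 15.0),
            "somatic": (70.0, 15.0),
            "decoy": (50.0, 20.0),
        }
    )
    ci_width_range: dict = field(
        default_factory=lambda: {
            "artifact": (80, 300),
            "germline": (0, 30),
            "somatic": (10, 60),
            "decoy": (0, 150),
        }
    )
    depth_nb_n: float = 10.0        # negative-binomial shape (overdispersion)
    depth_mean: float = 60.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TruthRow:
    id: str
    klass: int | None   # -1 / 1 / 2 / None (decoy)
    svtype: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    mode: str           # evidence mode: flag/centromere/donor/germline/somatic/decoy
    genotype: str = "het"


@dataclass
class TruthTable:
    """Planted SV id -> truth row; the ground truth for every planted call."""

    rows: dict[str, TruthRow] = field(default_factory=dict)

    def class_counts(self) -> dict:
        out: dict = {}
        for row in self.rows.values():
            key = "unlabeled" if row.klass is None else row.klass
            out.setdefault(key, {})
            out[key][row.svtype] = out[key].get(row.svtype, 0) + 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.rows.values()])
        df["klass"] = df["klass"].map(lambda k: "unlabeled" if pd.isna(k) else int(k))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        rows = {}
        for _, r in df.iterrows():
            rows[r["id"]] = TruthRow(
                id=r["id"],
                klass=None if r["klass"] == "unlabeled" else int(r["klass"]),
                svtype=r["svtype"],
                chrom1=r["chrom1"],
                pos1=int(r["pos1"]),
                chrom2=r["chrom2"],
                pos2=int(r["pos2"]),
                mode=r["mode"],
                genotype=r["genotype"],
            )
        return cls(rows=rows)


def planted_id(record_id: str) -> str:
    """Recover the planted truth id from a caller-qualified record id."""
    return record_id.split(":", 1)[-1].split(".")[0]


@dataclass
class ReferenceSet:
    fasta: Path
    centromere_bed: Path
    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]]   # 1-based inclusive
    tracts: list[tuple[str, int]]             # (chrom, 1-based tract start)
    tract_len: int


def generate_reference(config: CohortConfig, outdir: str | Path) -> ReferenceSet:
    """Write a deterministic random reference FASTA plus a centromere BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    p_gc = config.gc / 2.0
    probs = [(1 - config.gc) / 2, p_gc, p_gc, (1 - config.gc) / 2]

    chrom_lengths: dict[str, int] = {}
    centromeres: dict[str, tuple[int, int]] = {}
    tracts: list[tuple[str, int]] = []
    fasta_path = outdir / "reference.fa"
    bed_path = outdir / "centromeres.bed"

    with open(fasta_path, "w") as fa, open(bed_path, "w") as bed:
        for ci in range(config.n_chroms):
            chrom = f"chr{ci + 1}"
            L = config.chrom_len
            idx = rng.choice(4, size=L, p=probs)
            seq = _BASES[idx]
            cen_lo = int(config.centromere_span[0] * L) + 1
            cen_hi = int(config.centromere_span[1] * L)
            # plant poly-A tracts clear of the centromere
            for _ in range(config.n_lowc_tracts):
                while True:
                    start = int(rng.integers(1000, L - config.tract_len - 1000))
                    if not (cen_lo - config.tract_len <= start <= cen_hi):
                        break
                seq[start - 1 : start - 1 + config.tract_len] = b"A"
                tracts.append((chrom, start))
            chrom_lengths[chrom] = L
            centromeres[chrom] = (cen_lo, cen_hi)
            bed.write(f"{chrom}\t{cen_lo - 1}\t{cen_hi}\n")  # back to BED 0-based
            fa.write(f">{chrom}\n")
            raw = seq.tobytes().decode("ascii")
            for i in range(0, L, 60):
                fa.write(raw[i : i + 60])
                fa.write("\n")
    return ReferenceSet(
        fasta=fasta_path,
        centromere_bed=bed_path,
        chrom_lengths=chrom_lengths,
        centromeres=centromeres,
        tracts=tracts,
        tract_len=config.tract_len,
    )


# ---------------------------------------------------------------------------
# cohort planting

_VCF_HEADER = """##fileformat=VCFv4.2
{contigs}##FILTER=<ID=PCRPLUS_ENRICHED,Description="Enriched in PCR-plus batches">
##FILTER=<ID=VARIABLE_ACROSS_BATCHES,Description="Frequency varies across batches">
##FILTER=<ID=PREDICTED_GENOTYPING_ARTIFACT,Description="Predicted genotyping artifact">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="CI around POS">
##INFO=<ID=CIEND,Number=2,Type=Integer,Description="CI around END">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=CARRIERS,Number=1,Type=Integer,Description="Carrier count in cohort">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference-supporting reads">
##FORMAT=<ID=AO,Number=1,Type=Integer,Description="Alternate-supporting reads">
"""


def _vcf_header(chrom_lengths: dict[str, int], with_sample: bool) -> str:
    contigs = "".join(
        f"##contig=<ID={c},length={l}>\n" for c, l in chrom_lengths.items()
    )
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if with_sample:
        cols += "\tFORMAT\tSAMPLE1"
    return _VCF_HEADER.format(contigs=contigs) + cols + "\n"


@dataclass
class _Planted:
    """Internal: one planted SV with its sampling parameters."""

    row: TruthRow
    at_tract: bool = False


@dataclass
class CohortFiles:
    """Paths of everything one simulated cohort emits."""

    outdir: Path
    reference: ReferenceSet
    caller_vcfs: dict[str, Path]
    germline_panel: Path
    germline_phase3: Path
    hotspot_a: Path
    hotspot_b: Path
    donor_vcf: Path
    truth_path: Path
    truth: TruthTable
    config: CohortConfig


def _sample_interval(
    rng, config, chrom_lengths, centromeres, used, svtype,
    in_centromere=False, tract_anchor=None,
):
    """Rejection-sample an interval SV placement.

    Rejects candidates whose reciprocal overlap with any same-type planted
    interval reaches 0.8 (below the 0.9 match threshold with jitter headroom,
    so distinct planted SVs never cross-match), and keeps non-centromeric
    breakends clear of the centromere.
    """
    margin = 500
    for _ in range(2000):
        if tract_anchor is not None:
            chrom, start = tract_anchor
        else:
            chrom = f"chr{int(rng.integers(1, len(chrom_lengths) + 1))}"
            cen_lo, cen_hi = centromeres[chrom]
            if in_centromere:
                start = int(rng.integers(cen_lo + margin, cen_hi - margin))
            else:
                start = int(rng.integers(1000, chrom_lengths[chrom] - 1000))
        length = int(rng.integers(*config.sv_len_range))
        end = start + length
        if end > chrom_lengths[chrom] - 1000:
            if tract_anchor is not None:
                tract_anchor = None  # fall back to free placement
            continue
        cen_lo, cen_hi = centromeres[chrom]
        ends_in_cen = [
            cen_lo - margin <= p <= cen_hi + margin for p in (start, end)
        ]
        if in_centromere and not ends_in_cen[0]:
            continue
        if not in_centromere and any(ends_in_cen):
            if tract_anchor is not None:
                tract_anchor = None
            continue
        ok = True
        for (s, e) in used.get((chrom, svtype), []):
            inter = min(e, end) - max(s, start) + 1
            if inter > 0:
                ro = min(inter / (e - s + 1), inter / (end - start + 1))
                if ro >= 0.8:
                    ok = False
                    break
        if ok:
            used.setdefault((chrom, svtype), []).append((start, end))
            return chrom, start, end
    raise RuntimeError(
        "infeasible cohort config: could not place an interval SV "
        f"(svtype={svtype}, in_centromere={in_centromere})"
    )


def _sample_trs(
    rng, config, chrom_lengths, centromeres, used_trs,
    in_centromere=False, tract_anchor=None,
):
    margin = 500
    min_sep = 3 * (config.jitter + 1000)
    chroms = sorted(chrom_lengths)
    for _ in range(2000):
        if tract_anchor is not None:
            ca = tract_anchor[0]
            others = [c for c in chroms if c != ca]
            cb = others[int(rng.integers(len(others)))]
            pair = sorted((ca, cb))
        else:
            i, j = rng.choice(len(chroms), size=2, replace=False)
            pair = sorted((chroms[int(i)], chroms[int(j)]))
        c1, c2 = pair
        anchor_done = in_centromere is False  # centromere anchor placed once
        positions = {}
        for c in (c1, c2):
            cen_lo, cen_hi = centromeres[c]
            if tract_anchor is not None and c == tract_anchor[0]:
                positions[c] = tract_anchor[1]
                continue
            if in_centromere and not anchor_done:
                positions[c] = int(rng.integers(cen_lo + margin, cen_hi - margin))
                anchor_done = True
                continue
            p = int(rng.integers(1000, chrom_lengths[c] - 1000))
            if cen_lo - margin <= p <= cen_hi + margin:
                break
            positions[c] = p
        if len(positions) != 2:
            continue
        p1, p2 = positions[c1], positions[c2]
        ok = True
        for (q1, q2) in used_trs.get((c1, c2), []):
            if abs(q1 - p1) <= min_sep and abs(q2 - p2) <= min_sep:
                ok = False
                break
        if ok:
            used_trs.setdefault((c1, c2), []).append((p1, p2))
            return c1, p1, c2, p2
    raise RuntimeError("infeasible cohort config: could not place a TRS")


def _class_name(klass) -> str:
    return {-1: "artifact", 1: "germline", 2: "somatic", None: "decoy"}[klass]


def plant_sv_cohort(
    config: CohortConfig,
    outdir: str | Path,
    reference: ReferenceSet | None = None,
) -> CohortFiles:
    """Plant a full cohort and write every input file the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if reference is None:
        reference = generate_reference(config, outdir)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    chrom_lengths = reference.chrom_lengths
    centromeres = reference.centromeres
    tract_centers = [
        (c, s + reference.tract_len // 2) for c, s in reference.tracts
    ]
    used_intervals: dict = {}
    used_trs: dict = {}
    truth = TruthTable()
    planted: list[_Planted] = []
    nontrs_types = sorted(config.nontrs_mix)
    nontrs_probs = [config.nontrs_mix[t] for t in nontrs_types]
    nontrs_probs = [p / sum(nontrs_probs) for p in nontrs_probs]
    mode_names = sorted(config.artifact_mode_probs)
    mode_probs = [config.artifact_mode_probs[m] for m in mode_names]
    mode_probs = [p / sum(mode_probs) for p in mode_probs]

    counter = 0
    free_tracts = list(tract_centers)
    rng.shuffle(free_tracts)

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"sv{counter:05d}"

    for group in ("nonTRS", "TRS"):
        for klass, n in (
            (-1, config.n_artifact),
            (1, config.n_germline),
            (2, config.n_somatic),
            (None, config.n_decoy),
        ):
            for _ in range(n):
                cname = _class_name(klass)
                mode = cname
                in_cen = False
                tract_anchor = None
                if klass == -1:
                    mode = mode_names[
                        int(rng.choice(len(mode_names), p=mode_probs))
                    ]
                    in_cen = mode == "centromere"
                    if not in_cen and free_tracts and (
                        rng.random() < config.artifact_lowc_prob
                    ):
                        tract_anchor = free_tracts.pop()
                tid = next_id()
                genotype = "het"
                if klass == 1 and rng.random() >= config.germline_het_prob:
                    genotype = "hom"
                if group == "TRS":
                    c1, p1, c2, p2 = _sample_trs(
                        rng, config, chrom_lengths, centromeres, used_trs,
                        in_centromere=in_cen, tract_anchor=tract_anchor,
                    )
                    row = TruthRow(tid, klass, "TRS", c1, p1, c2, p2, mode, genotype)
                else:
                    svtype = nontrs_types[
                        int(rng.choice(len(nontrs_types), p=nontrs_probs))
                    ]
                    chrom, start, end = _sample_interval(
                        rng, config, chrom_lengths, centromeres, used_intervals,
                        svtype, in_centromere=in_cen,
                        tract_anchor=(
                            tract_anchor if tract_anchor is None else
                            (tract_anchor[0], tract_anchor[1])
                        ),
                    )
                    row = TruthRow(
                        tid, klass, svtype, chrom, start, chrom, end, mode, genotype
                    )
                truth.rows[tid] = row
                planted.append(_Planted(row=row, at_tract=tract_anchor is not None))

    files = _emit_cohort(config, outdir, reference, rng, planted)
    truth_path = outdir / "truth.tsv"
    truth.to_tsv(truth_path)
    _write_config_echo(config, outdir / "cohort_config.yaml")
    return CohortFiles(
        outdir=outdir,
        reference=reference,
        truth=truth,
        truth_path=truth_path,
        config=config,
        **files,
    )


def _write_config_echo(config: CohortConfig, path: Path) -> None:
    import yaml

    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _draw_reads(rng, config, klass: str, genotype: str) -> tuple[int, int]:
    """Class-conditional (ref, alt) read counts at one breakend."""
    p = config.depth_nb_n / (config.depth_nb_n + config.depth_mean)
    depth = int(rng.negative_binomial(config.depth_nb_n, p)) + 2
    if klass == "somatic":
        ratio = rng.normal(*config.somatic_read_ratio)
    elif klass == "artifact":
        ratio = rng.normal(*config.artifact_read_ratio)
    elif klass == "germline":
        ratio = 1.0 if genotype == "hom" else rng.normal(0.5, 0.04)
    else:  # decoy
        ratio = rng.uniform(0.1, 0.9)
    ratio = float(np.clip(ratio, 0.02, 1.0))
    alt = max(int(rng.binomial(depth, ratio)), 1)
    return depth - alt, alt


def _draw_ci(rng, config, klass: str) -> tuple[int, int]:
    lo, hi = config.ci_width_range[klass]
    w1 = int(rng.integers(lo, hi + 1))
    w2 = int(rng.integers(lo, hi + 1))
    return -w1, w2


def _emit_cohort(config, outdir, reference, rng, planted) -> dict:
    """Write caller VCFs, database VCFs/TSVs and the donor cohort."""
    chrom_lengths = reference.chrom_lengths
    caller_lines: dict[str, list] = {c: [] for c in config.callers}
    panel_lines: list = []
    phase3_lines: list = []
    donor_lines: list = []
    hotspot_rows: dict[str, list] = {"A": [], "B": []}

    def interval_line(
        chrom, pos, end, svtype, vid, qual, filt, info_extra, sample=None
    ):
        info = f"SVTYPE={svtype};END={end};SVLEN={end - pos}"
        if info_extra:
            info += ";" + info_extra
        cols = [chrom, str(pos), vid, "N", f"<{svtype}>", f"{qual:.1f}", filt, info]
        if sample is not None:
            cols += ["GT:GQ:RO:AO", sample]
        return (chrom, pos, "\t".join(cols))

    def bnd_lines(c1, p1, c2, p2, vid, qual, filt, ci1, ci2, sample=None):
        a_id, b_id = f"{vid}.a", f"{vid}.b"
        out = []
        for (ca, pa, cb, pb, this_id, mate_id, ci) in (
            (c1, p1, c2, p2, a_id, b_id, ci1),
            (c2, p2, c1, p1, b_id, a_id, ci2),
        ):
            info = f"SVTYPE=BND;MATEID={mate_id};CIPOS={ci[0]},{ci[1]}"
            cols = [
                ca, str(pa), this_id, "N", f"N[{cb}:{pb}[", f"{qual:.1f}", filt, info,
            ]
            if sample is not None:
                cols += ["GT:GQ:RO:AO", sample]
            out.append((ca, pa, "\t".join(cols)))
        return out

    for item in planted:
        row = item.row
        cname = _class_name(row.klass)

        # --- database / donor emission at true coordinates
        if row.klass == 1:
            in_panel = rng.random() < config.germline_panel_prob
            in_phase3 = rng.random() < config.germline_phase3_prob
            if not (in_panel or in_phase3):
                in_panel = True
            targets = []
            if in_panel:
                targets.append(panel_lines)
            if in_phase3:
                targets.append(phase3_lines)
            for target in targets:
                target.extend(
                    _db_lines(row, "PASS", f"AF={config.germline_af}")
                )
            if config.germline_donor_freq > 0:
                carriers = int(
                    rng.binomial(config.n_donors, config.germline_donor_freq)
                )
                if carriers > 0:
                    donor_lines.extend(
                        _db_lines(row, "PASS", f"CARRIERS={carriers}")
                    )
        elif row.klass == -1:
            if row.mode == "flag":
                flag = ARTIFACT_FLAG_CHOICES[
                    int(rng.integers(len(ARTIFACT_FLAG_CHOICES)))
                ]
                panel_lines.extend(_db_lines(row, flag, None))
            elif row.mode == "donor":
                carriers = max(
                    int(round(config.artifact_donor_freq * config.n_donors)), 2
                )
                donor_lines.extend(_db_lines(row, "PASS", f"CARRIERS={carriers}"))
            # centromere mode needs no database entry
        elif row.klass == 2:
            table = "A" if rng.random() < 0.5 else "B"
            hotspot_rows[table].append(
                (row.chrom1, row.pos1, row.chrom2, row.pos2, row.svtype, row.id)
            )

        # --- caller emission with jitter and class-conditional evidence
        detected = [c for c in config.callers if rng.random() < config.detection_prob]
        if not detected:
            detected = [config.callers[int(rng.integers(len(config.callers)))]]
        for caller in detected:
            j = config.jitter
            gq_mu, gq_sd = config.gq_params[cname]
            q_mu, q_sd = config.qual_params[cname]
            gq = max(int(round(rng.normal(gq_mu, gq_sd))), 1)
            qual = max(float(rng.normal(q_mu, q_sd)), 1.0)
            gt = "1/1" if row.genotype == "hom" else "0/1"
            vid = f"{row.id}.{caller}"
            if row.svtype == "TRS":
                p1 = row.pos1 + int(rng.integers(-j, j + 1)) if j else row.pos1
                p2 = row.pos2 + int(rng.integers(-j, j + 1)) if j else row.pos2
                ci1 = _draw_ci(rng, config, cname)
                ci2 = _draw_ci(rng, config, cname)
                ref1, alt1 = _draw_reads(rng, config, cname, row.genotype)
                sample = f"{gt}:{gq}:{ref1}:{alt1}"
                caller_lines[caller].extend(
                    bnd_lines(
                        row.chrom1, p1, row.chrom2, p2, vid, qual, "PASS",
                        ci1, ci2, sample,
                    )
                )
            else:
                s = row.pos1 + int(rng.integers(-j, j + 1)) if j else row.pos1
                e = row.pos2 + int(rng.integers(-j, j + 1)) if j else row.pos2
                ci1 = _draw_ci(rng, config, cname)
                ci2 = _draw_ci(rng, config, cname)
                ref_r, alt_r = _draw_reads(rng, config, cname, row.genotype)
                sample = f"{gt}:{gq}:{ref_r}:{alt_r}"
                info = (
                    f"CIPOS={ci1[0]},{ci1[1]};CIEND={ci2[0]},{ci2[1]}"
                )
                caller_lines[caller].append(
                    interval_line(
                        row.chrom1, s, e, row.svtype, vid, qual, "PASS", info, sample
                    )
                )

    paths: dict = {}
    caller_vcfs = {}
    for caller, lines in caller_lines.items():
        p = outdir / f"calls_{caller}.vcf"
        _write_vcf(p, chrom_lengths, lines, with_sample=True)
        caller_vcfs[caller] = p
    paths["caller_vcfs"] = caller_vcfs
    paths["germline_panel"] = outdir / "germline_panel.vcf"
    _write_vcf(paths["germline_panel"], chrom_lengths, panel_lines, with_sample=False)
    paths["germline_phase3"] = outdir / "germline_phase3.vcf"
    _write_vcf(paths["germline_phase3"], chrom_lengths, phase3_lines, with_sample=False)
    paths["donor_vcf"] = outdir / "donors.vcf"
    _write_vcf(paths["donor_vcf"], chrom_lengths, donor_lines, with_sample=False)
    for key, name in (("hotspot_a", "A"), ("hotspot_b", "B")):
        p = outdir / f"hotspots_{name}.tsv"
        with open(p, "w") as fh:
            fh.write("chrom1\tpos1\tchrom2\tpos2\tsvtype\tname\n")
            for r in hotspot_rows[name]:
                fh.write("\t".join(str(x) for x in r) + "\n")
        paths[key] = p
    return paths


def _db_lines(row: TruthRow, filt: str, info_extra: str | None) -> list:
    vid = f"db_{row.id}"
    if row.svtype == "TRS":
        out = []
        for (ca, pa, cb, pb, this_id, mate_id) in (
            (row.chrom1, row.pos1, row.chrom2, row.pos2, f"{vid}.a", f"{vid}.b"),
            (row.chrom2, row.pos2, row.chrom1, row.pos1, f"{vid}.b", f"{vid}.a"),
        ):
            info = f"SVTYPE=BND;MATEID={mate_id}"
            if info_extra:
                info += ";" + info_extra
            out.append(
                (ca, pa, f"{ca}\t{pa}\t{this_id}\tN\tN[{cb}:{pb}[\t.\t{filt}\t{info}")
            )
        return out
    info = f"SVTYPE={row.svtype};END={row.pos2};SVLEN={row.pos2 - row.pos1}"
    if info_extra:
        info += ";" + info_extra
    return [
        (
            row.chrom1,
            row.pos1,
            f"{row.chrom1}\t{row.pos1}\t{vid}\tN\t<{row.svtype}>\t.\t{filt}\t{info}",
        )
    ]


def _write_vcf(path: Path, chrom_lengths, lines, with_sample: bool) -> None:
    lines = sorted(lines, key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_lengths, with_sample))
        for _, _, line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# direct classifier harness

DEFAULT_INFORMATIVE = ("read_ratio", "gq", "cipos_width", "b1_entropy_k1")


def generate_separable_features(
    n_per_class: int = 667,
    shift: float = 2.5,
    seed: int = 0,
    group: str = "nonTRS",
    informative: tuple[str, ...] = DEFAULT_INFORMATIVE,
) -> pd.DataFrame:
    """Three-class feature table with a planted somatic mean shift.

    Class 2 is shifted by ``shift`` (in pooled-SD units) on the
    ``informative`` features; every other feature is pure noise. Class -1
    carries a small shift on ``qual`` so the artifact/germline axis is also
    learnable. The TRS group leaves ``log_length`` absent.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for klass in (-1, 1, 2):
        data = {
            name: rng.normal(0.0, 1.0, size=n_per_class) for name in FEATURE_NAMES
        }
        if klass == 2:
            for name in informative:
                data[name] = data[name] + shift
        if klass == -1:
            data["qual"] = data["qual"] - 1.0
        df = pd.DataFrame(data)
        df["klass"] = klass
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if group == "TRS":
        table["log_length"] = np.nan
    table["group"] = group
    return table
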