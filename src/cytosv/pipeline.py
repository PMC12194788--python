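"""End-to-end orchestration: QC -> consolidate -> label -> featurize -> train.

Each stage writes its output under the run directory with a manifest, so any
stage can be re-run from its recorded inputs. Reruns with the same config and
inputs are byte-identical. The run closes with a static HTML summary: class x
SV-type counts, per-group ROC curves, and feature distributions by class.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cytosv import classifier as clf
from cytosv.features import FEATURE_NAMES, extract_features
from cytosv.labeling import LabelContext, LabeledSV, build_truth_set
from cytosv.matching import MatchCriteria, consolidate_calls
from cytosv.qc import CYTOGENETIC_MIN_LEN, apply_basic_qc, filter_by_length
from cytosv.records import read_caller_vcf, read_database, write_sv_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for one end-to-end run."""

    caller_vcfs: dict[str, str]
    germline_panel: str
    germline_phase3: str
    hotspot_a: str
    hotspot_b: str
    donor_vcf: str
    centromere_bed: str
    reference_fasta: str
    outdir: str
    n_donors: int = 100
    min_len: int = CYTOGENETIC_MIN_LEN
    overlap_frac: float = 0.9
    bnd_dist: int = 1000
    donor_af_threshold: float = 0.01
    feature_window: int = 100
    seed: int = 0
    holdout_frac: float = 0.10
    test_frac_within_tune: float = 0.30
    importance_repeats: int = 5
    make_report: bool = True

    def criteria(self) -> MatchCriteria:
        return MatchCriteria(overlap_frac=self.overlap_frac, bnd_dist=self.bnd_dist)

    def validate(self) -> None:
        paths = [
            *self.caller_vcfs.values(),
            self.germline_panel,
            self.germline_phase3,
            self.hotspot_a,
            self.hotspot_b,
            self.donor_vcf,
            self.centromere_bed,
            self.reference_fasta,
        ]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError("config", f"missing input file(s): {missing}")

    @classmethod
    def from_cohort(cls, cohort, outdir: str | Path, **kwargs) -> "RunConfig":
        """Build a RunConfig from a simulated cohort's files."""
        return cls(
            caller_vcfs={c: str(p) for c, p in cohort.caller_vcfs.items()},
            germline_panel=str(cohort.germline_panel),
            germline_phase3=str(cohort.germline_phase3),
            hotspot_a=str(cohort.hotspot_a),
            hotspot_b=str(cohort.hotspot_b),
            donor_vcf=str(cohort.donor_vcf),
            centromere_bed=str(cohort.reference.centromere_bed),
            reference_fasta=str(cohort.reference.fasta),
            outdir=str(outdir),
            n_donors=cohort.config.n_donors,
            seed=cohort.config.seed,
            **kwargs,
        )


def feature_table(
    labeled: list[LabeledSV], reference, window: int = 100
) -> pd.DataFrame:
    """Assemble the model input table from labeled (consolidated) records."""
    rows = []
    for lab in labeled:
        fv = extract_features(lab.record, reference, window=window)
        row = fv.to_dict()
        row["id"] = lab.id
        row["svtype"] = lab.svtype
        row["group"] = "TRS" if lab.svtype == "TRS" else "nonTRS"
        row["klass"] = np.nan if lab.klass is None else lab.klass
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_NAMES + ["id", "svtype", "group", "klass"])


def run_end_to_end(config: RunConfig) -> dict:
    """Run every stage; return the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    try:
        result = _run_stages(config, outdir, manifest)
    except PipelineError as err:
        (outdir / "error.json").write_text(
            json.dumps({"stage": err.stage, "message": err.message})
        )
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def _stage(manifest, name, **counts):
    logger.info("stage %s: %s", name, counts)
    manifest["stages"][name] = counts


def _run_stages(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    import pyfaidx

    config.validate()
    criteria = config.criteria()

    # ---- read + QC
    try:
        per_caller = {}
        for caller, path in sorted(config.caller_vcfs.items()):
            per_caller[caller] = read_caller_vcf(path, caller)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("read", str(e))
    n_raw = sum(len(v) for v in per_caller.values())

    try:
        qc_reports = {}
        for caller in per_caller:
            kept, rep = apply_basic_qc(per_caller[caller])
            per_caller[caller] = filter_by_length(kept, config.min_len)
            qc_reports[caller] = {
                "n_input": rep.n_input,
                "n_kept_qc": rep.n_kept,
                "n_kept_length": len(per_caller[caller]),
                "removed": rep.removed,
            }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("qc", str(e))
    (outdir / "qc_report.json").write_text(json.dumps(qc_reports, indent=2, sort_keys=True))
    _stage(manifest, "qc", n_raw=n_raw,
           n_kept=sum(len(v) for v in per_caller.values()))

    # ---- consolidate
    try:
        consolidated = consolidate_calls(per_caller, criteria)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("consolidate", str(e))
    _stage(manifest, "consolidate", n_clusters=len(consolidated))

    # ---- label
    try:
        databases = (
            read_database(config.germline_panel, "germline_panel")
            + read_database(config.germline_phase3, "germline_phase3")
            + read_database(config.hotspot_a, "somatic_hotspot_A")
            + read_database(config.hotspot_b, "somatic_hotspot_B")
        )
        donors = read_database(config.donor_vcf, "donor_cohort")
        cen = read_database(config.centromere_bed, "centromere")
        ctx = LabelContext.from_centromere_entries(
            cen, donor_af_threshold=config.donor_af_threshold
        )
        labeled, summary = build_truth_set(
            consolidated, databases, donors, ctx,
            n_donors=config.n_donors, criteria=criteria,
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("label", str(e))
    labeled_path = outdir / "labeled.tsv"
    write_sv_table(labeled, labeled_path)
    summary_json = {str(k): v for k, v in sorted(summary.items(), key=lambda kv: str(kv[0]))}
    (outdir / "class_summary.json").write_text(json.dumps(summary_json, indent=2))
    _stage(manifest, "label", n_labeled=sum(
        1 for l in labeled if l.klass is not None))
    manifest["outputs"]["labeled"] = str(labeled_path)

    # ---- featurize
    try:
        reference = pyfaidx.Fasta(config.reference_fasta)
        table = feature_table(labeled, reference, window=config.feature_window)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("featurize", str(e))
    features_path = outdir / "features.tsv"
    table.to_csv(features_path, sep="\t", index=False)
    manifest["outputs"]["features"] = str(features_path)
    _stage(manifest, "featurize", n_rows=len(table))

    # ---- train + evaluate per group
    reports = {}
    rocs = {}
    for group in ("TRS", "nonTRS"):
        sub = table[(table["group"] == group) & table["klass"].notna()]
        try:
            plan = clf.SplitPlan(
                holdout_frac=config.holdout_frac,
                test_frac_within_tune=config.test_frac_within_tune,
                seed=config.seed,
            )
            train, test, holdout = clf.split_dataset(sub, plan)
            model = clf.train_classifier(train, test, group=group, seed=config.seed)
            report = clf.evaluate(model, holdout)
            report.importances = clf.feature_importance(
                model, holdout, n_repeats=config.importance_repeats, seed=config.seed
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"train_{group}", str(e))
        model_path = outdir / f"model_{group}.json"
        model.save(model_path)
        report_path = outdir / f"report_{group}.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        manifest["outputs"][f"model_{group}"] = str(model_path)
        manifest["outputs"][f"report_{group}"] = str(report_path)
        reports[group] = report
        proba = model.predict_proba(holdout)
        y = (holdout["klass"].astype(int) == 2).astype(int).to_numpy()
        rocs[group] = (y, proba[:, clf.SOMATIC_INDEX])
        _stage(
            manifest, f"train_{group}",
            n_train=len(train), n_test=len(test), n_holdout=len(holdout),
            somatic_auc=report.somatic_auc,
        )

    if config.make_report:
        try:
            _write_html_summary(outdir, summary_json, reports, rocs, table)
            manifest["outputs"]["summary_html"] = str(outdir / "summary.html")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("report", str(e))

    return {
        "manifest": manifest,
        "labeled": labeled,
        "summary": summary,
        "features": table,
        "reports": reports,
    }


def _write_html_summary(outdir, summary_json, reports, rocs, table) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (group, (y, scores)) in zip(axes, sorted(rocs.items())):
        fpr, tpr, _ = roc_curve(y, scores)
        ax.plot(fpr, tpr, label=f"somatic AUC={reports[group].somatic_auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_title(f"{group}: somatic one-vs-rest ROC")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "roc.png", dpi=100)
    plt.close(fig)

    feat_cols = ["read_ratio", "gq", "cipos_width", "b1_entropy_k1"]
    fig, axes = plt.subplots(1, len(feat_cols), figsize=(4 * len(feat_cols), 3))
    labeled = table[table["klass"].notna()]
    for ax, col in zip(np.atleast_1d(axes), feat_cols):
        for klass, name in ((-1, "artifact"), (1, "germline"), (2, "somatic")):
            vals = labeled.loc[labeled["klass"] == klass, col].dropna()
            if len(vals):
                ax.hist(vals, bins=25, alpha=0.5, label=name, density=True)
        ax.set_title(col)
    np.atleast_1d(axes)[0].legend()
    fig.tight_layout()
    fig.savefig(outdir / "features.png", dpi=100)
    plt.close(fig)

    rows = []
    for klass, by_type in summary_json.items():
        for svtype, n in sorted(by_type.items()):
            rows.append(f"<tr><td>{klass}</td><td>{svtype}</td><td>{n}</td></tr>")
    metrics = []
    for group, rep in sorted(reports.items()):
        metrics.append(
            f"<tr><td>{group}</td><td>{rep.macro_auc:.3f}</td>"
            f"<td>{rep.micro_auc:.3f}</td><td>{rep.somatic_auc:.3f}</td>"
            f"<td>{rep.sensitivity:.3f}</td><td>{rep.specificity:.3f}</td></tr>"
        )
    html = f"""<html><head><title>cytosv run summary</title></head><body>
<h1>SV classification run summary</h1>
<h2>Class x SV-type counts</h2>
<table border=1><tr><th>class</th><th>svtype</th><th>n</th></tr>{''.join(rows)}</table>
<h2>Model performance (hold-out)</h2>
<table border=1><tr><th>group</th><th>macro AUC</th><th>micro AUC</th>
<th>somatic AUC</th><th>sensitivity</th><th>specificity</th></tr>{''.join(metrics)}</table>
<h2>ROC curves</h2><img src="roc.png">
<h2>Feature distributions by class</h2><img src="features.png">
</body></html>"""
    (outdir / "summary.html").write_text(html)
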