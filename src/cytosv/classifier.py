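"""Three-class SV classifier: gradient boosting, AUC metrics, Youden points.

Translocations (TRS) and interval SVs are trained as separate models because
their feature distributions differ structurally (no length, two independent
breakend contexts). Data are split 90/10 into a tuning set and a hold-out
set, and the tuning set 70/30 into train and test; the test fold drives early
stopping. Reported metrics: macro-AUC (unweighted mean of one-vs-rest AUCs),
micro-AUC (pooled one-hot indicator expansion), the somatic one-vs-rest AUC,
and the sensitivity/specificity at the threshold maximizing their sum
(the Youden point).
"""

from __future__ import annotations

import base64
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from cytosv.features import FEATURE_NAMES
from cytosv.labeling import ARTIFACT, GERMLINE, SOMATIC

logger = logging.getLogger(__name__)

CLASS_ORDER = (ARTIFACT, GERMLINE, SOMATIC)  # -> model indices 0, 1, 2
SOMATIC_INDEX = CLASS_ORDER.index(SOMATIC)

DEFAULT_PARAMS = {
    "objective": "multi:softprob",
    "num_class": len(CLASS_ORDER),
    "eval_metric": "mlogloss",
    "eta": 0.1,
    "max_depth": 4,
    "min_child_weight": 2,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "tree_method": "hist",
    "nthread": 1,
}
DEFAULT_NUM_ROUNDS = 400
DEFAULT_EARLY_STOPPING = 25


@dataclass
class SplitPlan:
    """Hold-out and train/test fractions, stratified by class."""

    holdout_frac: float = 0.10
    test_frac_within_tune: float = 0.30
    seed: int = 0
    stratify_by: str = "klass"

    def __post_init__(self) -> None:
        for name in ("holdout_frac", "test_frac_within_tune"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")


@dataclass
class ModelReport:
    """Per-group evaluation summary."""

    group: str
    macro_auc: float | None
    micro_auc: float
    somatic_auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    importances: dict[str, float] = field(default_factory=dict)
    n_per_class: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "group": self.group,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "somatic_auc": self.somatic_auc,
            "youden_threshold": self.youden_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "importances": dict(self.importances),
            "n_per_class": {str(k): v for k, v in self.n_per_class.items()},
        }
        return d


@dataclass
class SVClassifierModel:
    """A self-describing fitted model artifact.

    Records everything needed to reproduce predictions: the booster, feature
    order, per-feature imputation medians from the training set, seed and
    hyperparameters.
    """

    booster: xgb.Booster
    feature_names: list[str]
    medians: dict[str, float]
    seed: int
    params: dict
    group: str

    def _impute(self, table: pd.DataFrame) -> pd.DataFrame:
        X = table[self.feature_names].astype(float).copy()
        for name in self.feature_names:
            med = self.medians.get(name)
            if med is not None and not np.isnan(med):
                X[name] = X[name].fillna(med)
        return X

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = self._impute(table)
        dmat = xgb.DMatrix(X.values, feature_names=self.feature_names, nthread=1)
        return self.booster.predict(dmat)

    def save(self, path: str | Path) -> None:
        raw = self.booster.save_raw(raw_format="json")
        payload = {
            "format": "cytosv-model-v1",
            "group": self.group,
            "feature_names": self.feature_names,
            "medians": self.medians,
            "seed": self.seed,
            "params": self.params,
            "booster_b64": base64.b64encode(bytes(raw)).decode("ascii"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SVClassifierModel":
        payload = json.loads(Path(path).read_text())
        booster = xgb.Booster()
        booster.load_model(bytearray(base64.b64decode(payload["booster_b64"])))
        return cls(
            booster=booster,
            feature_names=payload["feature_names"],
            medians=payload["medians"],
            seed=payload["seed"],
            params=payload["params"],
            group=payload["group"],
        )


def _check_classes(table: pd.DataFrame) -> None:
    present = set(table["klass"].unique())
    missing = [k for k in CLASS_ORDER if k not in present]
    if missing:
        raise ValueError(f"class(es) absent from the data: {missing}")


def split_dataset(
    table: pd.DataFrame, plan: SplitPlan
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified (train, test, holdout) split of a labeled feature table.

    ``table`` must carry a ``klass`` column with all three classes present;
    unlabeled rows (klass NaN) are excluded before splitting. The split is
    deterministic for a fixed ``plan.seed``.
    """
    table = table[table["klass"].notna()].copy()
    table["klass"] = table["klass"].astype(int)
    _check_classes(table)
    tune, holdout = train_test_split(
        table,
        test_size=plan.holdout_frac,
        stratify=table[plan.stratify_by],
        random_state=plan.seed,
    )
    train, test = train_test_split(
        tune,
        test_size=plan.test_frac_within_tune,
        stratify=tune[plan.stratify_by],
        random_state=plan.seed,
    )
    return train, test, holdout


def _to_matrix(
    table: pd.DataFrame, feature_names: list[str], medians: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    X = table[feature_names].astype(float).copy()
    for name in feature_names:
        med = medians.get(name)
        if med is not None and not np.isnan(med):
            X[name] = X[name].fillna(med)
    y = np.array([CLASS_ORDER.index(k) for k in table["klass"].astype(int)])
    return X.values, y


def train_classifier(
    train: pd.DataFrame,
    test: pd.DataFrame,
    group: str,
    seed: int = 0,
    params: dict | None = None,
    num_rounds: int = DEFAULT_NUM_ROUNDS,
    early_stopping_rounds: int = DEFAULT_EARLY_STOPPING,
    feature_names: list[str] | None = None,
) -> SVClassifierModel:
    """Fit a gradient-boosted multiclass model with early stopping on test.

    Training is reproducible bit-for-bit for a fixed seed (single thread,
    exact histogram construction, fixed row order by sorted index).
    """
    _check_classes(train)
    if feature_names is None:
        feature_names = [c for c in FEATURE_NAMES if c in train.columns]
    full_params = dict(DEFAULT_PARAMS)
    if params:
        full_params.update(params)
    full_params["seed"] = seed

    # sort so row order never depends on upstream shuffling
    train = train.sort_index()
    test = test.sort_index()
    medians = {}
    for name in feature_names:
        col = train[name].astype(float)
        medians[name] = float(col.median()) if col.notna().any() else float("nan")
    X_tr, y_tr = _to_matrix(train, feature_names, medians)
    X_te, y_te = _to_matrix(test, feature_names, medians)
    dtrain = xgb.DMatrix(X_tr, label=y_tr, feature_names=feature_names, nthread=1)
    dtest = xgb.DMatrix(X_te, label=y_te, feature_names=feature_names, nthread=1)
    booster = xgb.train(
        full_params,
        dtrain,
        num_boost_round=num_rounds,
        evals=[(dtest, "test")],
        early_stopping_rounds=early_stopping_rounds,
        verbose_eval=False,
    )
    return SVClassifierModel(
        booster=booster,
        feature_names=feature_names,
        medians=medians,
        seed=seed,
        params=full_params,
        group=group,
    )


def youden_optimal(
    scores, labels
) -> tuple[float, float, float]:
    """Threshold on ``scores`` maximizing sensitivity + specificity.

    A record is called positive when its score is >= the threshold; the
    threshold is chosen from the observed scores, ties broken toward the
    smaller threshold (higher sensitivity). Returns
    ``(threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("youden_optimal needs both classes present")
    best = None
    for t in sorted(set(scores.tolist())):
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum() / n_pos)
        spec = float((~pred & (labels == 0)).sum() / n_neg)
        j = sens + spec
        # strict > keeps the smallest threshold on ties
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return float(t), sens, spec


def evaluate(model: SVClassifierModel, holdout: pd.DataFrame) -> ModelReport:
    """Score a hold-out table and compute the report metrics.

    Classes absent from the hold-out are dropped from the macro average with
    a warning; the somatic AUC and Youden point require class 2 and at least
    one other class.
    """
    holdout = holdout[holdout["klass"].notna()]
    proba = model.predict_proba(holdout)
    y = np.array([CLASS_ORDER.index(k) for k in holdout["klass"].astype(int)])
    onehot = np.eye(len(CLASS_ORDER))[y]

    per_class = []
    for idx, klass in enumerate(CLASS_ORDER):
        if (y == idx).sum() in (0, len(y)):
            logger.warning(
                "class %s absent from holdout; dropped from macro-AUC", klass
            )
            continue
        per_class.append(roc_auc_score((y == idx).astype(int), proba[:, idx]))
    macro_auc = float(np.mean(per_class)) if per_class else None
    micro_auc = float(roc_auc_score(onehot.ravel(), proba.ravel()))
    somatic_scores = proba[:, SOMATIC_INDEX]
    somatic_labels = (y == SOMATIC_INDEX).astype(int)
    somatic_auc = float(roc_auc_score(somatic_labels, somatic_scores))
    threshold, sens, spec = youden_optimal(somatic_scores, somatic_labels)

    counts = {
        klass: int((y == idx).sum()) for idx, klass in enumerate(CLASS_ORDER)
    }
    return ModelReport(
        group=model.group,
        macro_auc=macro_auc,
        micro_auc=micro_auc,
        somatic_auc=somatic_auc,
        youden_threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        n_per_class=counts,
    )


def feature_importance(
    model: SVClassifierModel,
    holdout: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance: mean drop in somatic one-vs-rest AUC.

    Each feature column of the hold-out is shuffled ``n_repeats`` times and
    the drop in the somatic AUC is averaged; deterministic for a fixed seed.
    """
    holdout = holdout[holdout["klass"].notna()]
    y = np.array([CLASS_ORDER.index(k) for k in holdout["klass"].astype(int)])
    somatic_labels = (y == SOMATIC_INDEX).astype(int)
    base_auc = roc_auc_score(
        somatic_labels, model.predict_proba(holdout)[:, SOMATIC_INDEX]
    )
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    X = holdout.copy()
    for name in model.feature_names:
        drops = []
        original = X[name].to_numpy(copy=True)
        for _ in range(n_repeats):
            X[name] = rng.permutation(original)
            auc = roc_auc_score(
                somatic_labels, model.predict_proba(X)[:, SOMATIC_INDEX]
            )
            drops.append(base_auc - auc)
        X[name] = original
        out[name] = float(np.mean(drops))
    return out
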