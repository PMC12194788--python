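import itertools

import numpy as np
import pandas as pd
import pytest

from cytosv import classifier as clf
from cytosv.simulate import generate_separable_features


def brute_force_auc(scores, labels) -> float:
    """Mann-Whitney pairwise-comparison AUC oracle."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    best = None
    for t in sorted(set(scores)):
        pred = [s >= t for s in scores]
        sens = sum(p and l for p, l in zip(pred, labels)) / sum(labels)
        spec = sum((not p) and (not l) for p, l in zip(pred, labels)) / (
            len(labels) - sum(labels)
        )
        if best is None or sens + spec > best[0] + 1e-12:
            best = (sens + spec, t, sens, spec)
    return best[1:]


@pytest.fixture(scope="module")
def fitted():
    table = generate_separable_features(300, 2.5, seed=5)
    train, test, holdout = clf.split_dataset(table, clf.SplitPlan(seed=5))
    model = clf.train_classifier(train, test, group="nonTRS", seed=5)
    return model, train, test, holdout


class TestSplit:
    def make_table(self, n):
        rng = np.random.default_rng(0)
        counts = [n - 2 * (n // 3), n // 3, n // 3]
        klass = np.repeat([-1, 1, 2], counts)
        return pd.DataFrame({"x": rng.normal(size=n), "klass": klass})

    def test_paper_fractions_on_1000_records(self):
        train, test, holdout = clf.split_dataset(
            self.make_table(1000), clf.SplitPlan(seed=3)
        )
        assert (len(train), len(test), len(holdout)) == (630, 270, 100)

    def test_deterministic_for_fixed_seed(self):
        t1 = clf.split_dataset(self.make_table(600), clf.SplitPlan(seed=9))
        t2 = clf.split_dataset(self.make_table(600), clf.SplitPlan(seed=9))
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a, b)

    def test_stratification_within_two_records_of_global(self):
        table = self.make_table(1000)
        global_frac = table["klass"].value_counts(normalize=True)
        for part in clf.split_dataset(table, clf.SplitPlan(seed=1)):
            counts = part["klass"].value_counts()
            for k in (-1, 1, 2):
                expected = global_frac[k] * len(part)
                assert abs(counts[k] - expected) <= 2

    def test_missing_class_is_named(self):
        table = self.make_table(300)
        table = table[table["klass"] != 2]
        with pytest.raises(ValueError, match="2"):
            clf.split_dataset(table, clf.SplitPlan(seed=0))

    def test_splits_are_disjoint_and_exhaustive(self):
        table = self.make_table(500)
        train, test, holdout = clf.split_dataset(table, clf.SplitPlan(seed=4))
        idx = sorted([*train.index, *test.index, *holdout.index])
        assert idx == sorted(table.index)


class TestYouden:
    def test_perfect_separation(self):
        t, sens, spec = clf.youden_optimal([0.1, 0.2, 0.7, 0.8], [0, 0, 1, 1])
        assert (t, sens, spec) == (0.7, 1.0, 1.0)

    def test_inverted_two_points_sacrifices_one_side(self):
        t, sens, spec = clf.youden_optimal([0.9, 0.1], [0, 1])
        assert sens + spec == pytest.approx(1.0)
        assert t == 0.1  # tie toward the smaller threshold (sens 1, spec 0)

    def test_all_equal_scores_classify_all_positive(self):
        t, sens, spec = clf.youden_optimal([0.5, 0.5, 0.5], [0, 1, 1])
        assert (t, sens, spec) == (0.5, 1.0, 0.0)

    def test_one_class_labels_raise(self):
        with pytest.raises(ValueError):
            clf.youden_optimal([0.1, 0.2], [1, 1])

    def test_agrees_with_exhaustive_search_on_random_sets(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.1, 0.25, 0.5, 0.51, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            got = clf.youden_optimal(scores, labels)
            want = brute_force_youden(scores.tolist(), labels.tolist())
            assert got == pytest.approx(want)


class TestTrainEvaluate:
    def test_separable_data_beats_chance_and_is_deterministic(self, fitted):
        model, train, test, holdout = fitted
        report = clf.evaluate(model, holdout)
        assert report.somatic_auc > 0.95
        assert report.macro_auc is not None and 0 <= report.macro_auc <= 1
        # permuted row order, same seed -> identical predictions
        shuffled = train.sample(frac=1.0, random_state=7)
        model2 = clf.train_classifier(shuffled, test, group="nonTRS", seed=5)
        np.testing.assert_array_equal(
            model.predict_proba(holdout), model2.predict_proba(holdout)
        )

    def test_single_class_training_set_raises(self, fitted):
        _, train, test, _ = fitted
        only_somatic = train[train["klass"] == 2]
        with pytest.raises(ValueError):
            clf.train_classifier(only_somatic, test, group="nonTRS", seed=0)

    def test_auc_agrees_with_pairwise_oracle_on_small_holdout(self, fitted):
        model, _, _, holdout = fitted
        small = holdout.head(50)
        proba = model.predict_proba(small)
        y = (small["klass"] == 2).astype(int).tolist()
        scores = proba[:, clf.SOMATIC_INDEX].tolist()
        report = clf.evaluate(model, small)
        assert report.somatic_auc == pytest.approx(brute_force_auc(scores, y))

    def test_model_round_trips_through_save_load(self, fitted, tmp_path):
        model, _, _, holdout = fitted
        path = tmp_path / "model.json"
        model.save(path)
        loaded = clf.SVClassifierModel.load(path)
        np.testing.assert_allclose(
            model.predict_proba(holdout), loaded.predict_proba(holdout)
        )
        assert loaded.medians == model.medians
        assert loaded.group == "nonTRS"

    def test_absent_holdout_class_drops_macro_term_with_warning(self, fitted, caplog):
        model, _, _, holdout = fitted
        no_artifact = holdout[holdout["klass"] != -1]
        with caplog.at_level("WARNING"):
            report = clf.evaluate(model, no_artifact)
        assert "absent" in caplog.text
        assert report.macro_auc is not None  # mean over the two present classes


class TestCrossCohortTransfer:
    def test_transfer_auc_not_above_same_cohort_holdout(self):
        """A model applied to a noisier external cohort should not beat its
        own same-cohort hold-out performance (beyond rounding)."""
        cohort_a = generate_separable_features(400, 2.5, seed=201)
        train, test, holdout = clf.split_dataset(cohort_a, clf.SplitPlan(seed=201))
        model = clf.train_classifier(train, test, group="nonTRS", seed=201)
        same_auc = clf.evaluate(model, holdout).somatic_auc
        # external cohort: weaker planted signal (perturbed noise conditions)
        cohort_b = generate_separable_features(400, 1.5, seed=202)
        transfer_auc = clf.evaluate(model, cohort_b).somatic_auc
        assert transfer_auc <= same_auc + 0.02


class TestFeatureImportance:
    def test_noise_feature_near_zero_and_signal_ranked_first(self):
        table = generate_separable_features(
            250, 3.0, seed=11, informative=("read_ratio",)
        )
        train, test, holdout = clf.split_dataset(table, clf.SplitPlan(seed=11))
        model = clf.train_classifier(train, test, group="nonTRS", seed=11)
        imp = clf.feature_importance(model, holdout, n_repeats=5, seed=11)
        ranked = sorted(imp, key=imp.get, reverse=True)
        assert ranked[0] == "read_ratio"
        noise = [v for k, v in imp.items() if k != "read_ratio"]
        assert max(abs(v) for v in noise) < 0.1

    def test_duplicated_column_importance_not_above_single(self):
        base = generate_separable_features(250, 3.0, seed=13, informative=("read_ratio",))
        dup = base.copy()
        dup["gq"] = dup["read_ratio"]  # duplicate the signal into a second column

        def somatic_importance(table, features):
            train, test, holdout = clf.split_dataset(table, clf.SplitPlan(seed=13))
            model = clf.train_classifier(
                train, test, group="nonTRS", seed=13, feature_names=features
            )
            return clf.feature_importance(model, holdout, n_repeats=5, seed=13)

        features = [c for c in base.columns if c not in ("klass", "group")]
        imp_single = somatic_importance(base, features)
        imp_dup = somatic_importance(dup, features)
        assert imp_dup["read_ratio"] <= imp_single["read_ratio"] + 0.02
        assert imp_dup["gq"] <= imp_single["read_ratio"] + 0.02

    def test_deterministic_for_fixed_seed(self):
        table = generate_separable_features(150, 2.0, seed=3)
        train, test, holdout = clf.split_dataset(table, clf.SplitPlan(seed=3))
        model = clf.train_classifier(train, test, group="nonTRS", seed=3)
        i1 = clf.feature_importance(model, holdout, n_repeats=3, seed=3)
        i2 = clf.feature_importance(model, holdout, n_repeats=3, seed=3)
        assert i1 == i2
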