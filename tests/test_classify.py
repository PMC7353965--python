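"""Supervised protocol: set assembly, folds, SMOTE, hyper-parameters, metrics."""

import math

import numpy as np
import pytest

import netpclass as npc
from netpclass import classify
from netpclass.classify import HYPERPARAMETER_GRID
from netpclass.structure_io import LabelTable


def _labels(spec):
    """Build a LabelTable from {label: count}."""
    entries = {}
    i = 0
    for label, count in spec.items():
        for _ in range(count):
            entries[f"d{i}"] = label
            i += 1
    return LabelTable(entries)


class TestAssemblePSNSets:
    def test_small_child_dropped(self):
        sets = npc.assemble_psn_sets(_labels({"1.A": 40, "1.B": 35, "1.C": 10}), hierarchy_level=1)
        assert len(sets) == 1
        assert sets[0].classes == ["1.A", "1.B"]
        assert len(sets[0]) == 75

    def test_single_valid_child_emits_nothing(self):
        sets = npc.assemble_psn_sets(_labels({"1.A": 40, "1.C": 10}), hierarchy_level=1)
        assert sets == []

    def test_boundary_thirty(self):
        sets = npc.assemble_psn_sets(_labels({"1.A": 30, "1.B": 30}), hierarchy_level=1)
        assert len(sets) == 1

    def test_top_level_grouping(self):
        table = _labels({"1.A": 35, "1.B": 30, "2.A": 40, "2.B": 5})
        sets = npc.assemble_psn_sets(table, hierarchy_level=0)
        # at level 0 children are the top classes "1" (65) and "2" (45)
        assert len(sets) == 1
        assert sets[0].classes == ["1", "2"]


class TestStratifiedFolds:
    def test_proportions_preserved(self):
        y = np.array(["a"] * 60 + ["b"] * 40)
        folds = npc.stratified_folds(y, k=10, seed=0)
        for f in range(10):
            members = y[folds == f]
            assert (members == "a").sum() == 6
            assert (members == "b").sum() == 4

    def test_deterministic_under_seed(self):
        y = np.array(["a"] * 30 + ["b"] * 30)
        np.testing.assert_array_equal(
            npc.stratified_folds(y, seed=5), npc.stratified_folds(y, seed=5)
        )

    def test_rounding_split(self):
        y = np.array(["a"] * 61 + ["b"] * 40)
        folds = npc.stratified_folds(y, k=10, seed=1)
        counts = [np.sum((y == "a") & (folds == f)) for f in range(10)]
        assert set(counts) <= {6, 7}
        sizes = [np.sum(folds == f) for f in range(10)]
        assert max(sizes) - min(sizes) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            npc.stratified_folds(np.array(["a"] * 50 + ["b"] * 5), k=10)


class TestSMOTE:
    def test_balances_90_30(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 4))
        y = np.array(["maj"] * 90 + ["min"] * 30)
        Xa, ya = npc.smote_oversample(X, y, seed=0)
        assert (ya == "maj").sum() == 90
        assert (ya == "min").sum() == 90

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        y = np.array(["a"] * 50 + ["b"] * 50)
        Xa, ya = npc.smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(Xa, X)
        np.testing.assert_array_equal(ya, y)

    def test_synthetic_points_on_minority_segments(self):
        """Every synthetic point lies on a segment between two originals of
        its own class."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = np.array(["maj"] * 45 + ["min"] * 15)
        Xa, ya = npc.smote_oversample(X, y, seed=3)
        originals = X[y == "min"]
        synthetic = Xa[len(X):]
        assert (ya[len(X):] == "min").all()
        for point in synthetic:
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    v, w = originals[i], originals[j]
                    seg = w - v
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    t = (point - v) @ seg / denom
                    if 0 <= t <= 1 and np.linalg.norm(v + t * seg - point) < 1e-9:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_originals_retained_first(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = np.array(["a"] * 30 + ["b"] * 10)
        Xa, _ = npc.smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(Xa[:40], X)

    def test_singleton_class_rejected(self):
        X = np.zeros((11, 2))
        y = np.array(["a"] * 10 + ["b"])
        with pytest.raises(ValueError):
            npc.smote_oversample(X, y)


class TestHyperparameterSelection:
    def test_grid_has_expected_five_values(self):
        assert HYPERPARAMETER_GRID == (0.25, 0.5, 1.0, 2.0, 4.0)

    def test_all_ties_return_smallest(self):
        """Perfectly separable data scores 100% for every grid value."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, size=(30, 2)), rng.normal(10, 0.1, size=(30, 2))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        assert npc.select_hyperparameter(X, y, seed=0) == 0.25

    def test_matches_exhaustive_reevaluation(self):
        """The returned value is the argmax of the same inner-CV score."""
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 2.0, size=(40, 8)), rng.normal(0.8, 2.0, size=(40, 8))])
        y = np.array(["a"] * 40 + ["b"] * 40)
        chosen = npc.select_hyperparameter(X, y, seed=2)
        scores = {}
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=2)
        splits = list(skf.split(X, y))
        for value in HYPERPARAMETER_GRID:
            accs = []
            for tr, va in splits:
                scaler, model = classify._fit_on_training(X[tr], y[tr], value, "proportional", 2)
                accs.append(npc.accuracy(model.predict(scaler.transform(X[va])), y[va]))
            scores[value] = np.mean(accs)
        best = max(scores.values())
        smallest_argmax = min(v for v, s in scores.items() if s >= best - 1e-12)
        assert chosen == smallest_argmax


class TestTrainAndMetrics:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.2, size=(25, 3)), rng.normal(8, 0.2, size=(25, 3))])
        y = np.array(["a"] * 25 + ["b"] * 25)
        model = npc.train_ovr_logistic(X, y, 1.0)
        assert npc.accuracy(model.predict(X), y) == 100.0

    def test_probabilities_valid(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = np.array(["a", "b", "c"] * 20)
        model = npc.train_ovr_logistic(X, y, 1.0)
        proba = model.predict_proba(X)
        assert proba.shape == (60, 3)
        assert ((proba >= 0) & (proba <= 1)).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_one_hot_identity_design(self):
        X = np.eye(3).repeat(12, axis=0)
        y = np.array(["a", "b", "c"]).repeat(12)
        model = npc.train_ovr_logistic(X, y, 4.0)
        assert npc.accuracy(model.predict(np.eye(3)), ["a", "b", "c"]) == 100.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            npc.train_ovr_logistic(np.zeros((10, 2)), ["a"] * 10, 1.0)

    @pytest.mark.parametrize("pred, truth, expected", [
        (["a", "a"], ["a", "a"], 100.0),
        (["a", "a"], ["b", "b"], 0.0),
        (["a", "a", "a", "b"], ["a", "a", "a", "a"], 75.0),
    ])
    def test_accuracy(self, pred, truth, expected):
        assert npc.accuracy(pred, truth) == expected

    def test_accuracy_empty_rejected(self):
        with pytest.raises(ValueError):
            npc.accuracy([], [])

    def test_mcc_perfect_and_inverted(self):
        assert npc.mcc(["a", "b"] * 10, ["a", "b"] * 10) == pytest.approx(1.0)
        assert npc.mcc(["b", "a"] * 10, ["a", "b"] * 10) == pytest.approx(-1.0)

    def test_mcc_matches_binary_formula(self):
        tp, fn, fp, tn = 50, 10, 10, 30
        truth = ["p"] * (tp + fn) + ["n"] * (fp + tn)
        pred = ["p"] * tp + ["n"] * fn + ["p"] * fp + ["n"] * tn
        expected = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert npc.mcc(pred, truth) == pytest.approx(expected)

    def test_mcc_degenerate_zero(self):
        assert npc.mcc(["a"] * 10, ["a"] * 10) == 0.0


class TestRunProtocol:
    def _separable(self, n_per_class=60, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(0, 0.5, size=(n_per_class, 4)),
            rng.normal(5, 0.5, size=(n_per_class, 4)),
        ])
        y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
        return X, y

    def test_separable_classes_high_accuracy(self):
        X, y = self._separable()
        result = npc.run_protocol(X, y, seed=0)
        assert result.accuracy_mean >= 95.0

    def test_shuffled_labels_near_chance(self):
        """Labels independent of features: accuracy within 3 binomial SEs of 50%."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 6))
        y = np.array(["a"] * 60 + ["b"] * 60)
        result = npc.run_protocol(X, y, seed=0)
        se = 100 * math.sqrt(0.25 / 120)
        assert abs(result.accuracy_mean - 50.0) <= 3 * se

    def test_deterministic_under_seed(self):
        X, y = self._separable(30)
        a = npc.run_protocol(X, y, seed=3, n_folds=5)
        b = npc.run_protocol(X, y, seed=3, n_folds=5)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)
        np.testing.assert_array_equal(a.fold_mccs, b.fold_mccs)
        assert a.chosen_hyperparameters == b.chosen_hyperparameters

    def test_no_test_fold_leakage(self, monkeypatch):
        """Neither hyper-parameter selection nor model fitting ever sees a
        row of the held-out fold (rows fingerprinted by a unique column)."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        X[:, 0] = np.arange(60)  # unique fingerprint per row
        y = np.array(["a", "b"] * 30)

        events = []  # ordered ("select"|"fit", row fingerprints) log
        orig_select = classify.select_hyperparameter
        orig_fit = classify._fit_on_training

        def spy_select(X_train, y_train, **kwargs):
            events.append(("select", set(np.asarray(X_train)[:, 0].tolist())))
            return orig_select(X_train, y_train, **kwargs)

        def spy_fit(X_train, y_train, value, mode, seed):
            events.append(("fit", set(np.asarray(X_train)[:, 0].tolist())))
            return orig_fit(X_train, y_train, value, mode, seed)

        monkeypatch.setattr(classify, "select_hyperparameter", spy_select)
        monkeypatch.setattr(classify, "_fit_on_training", spy_fit)
        result = npc.run_protocol(X, y, mode="proportional+smote", seed=0, n_folds=5)

        # each outer fold opens with one "select"; every data access until the
        # next "select" (inner CV fits, SMOTE, the final fit) belongs to it
        fold = -1
        n_selects = 0
        for kind, fingerprints in events:
            if kind == "select":
                fold += 1
                n_selects += 1
            test_fingerprints = set(X[result.test_indices[fold], 0].tolist())
            assert fingerprints.isdisjoint(test_fingerprints)
        assert n_selects == 5

    def test_smote_only_in_smote_mode(self, monkeypatch):
        X, y = self._separable(20)

        def boom(*args, **kwargs):
            raise AssertionError("SMOTE must not run in proportional mode")

        monkeypatch.setattr(classify, "smote_oversample", boom)
        npc.run_protocol(X, y, mode="proportional", seed=0, n_folds=4)

    def test_mcc_positive_when_accuracy_beats_chance(self):
        X, y = self._separable()
        result = npc.run_protocol(X, y, seed=1)
        assert result.accuracy_mean > 50.0
        assert result.mcc_mean > 0.0


class TestModelResultsShape:
    def test_model_fit_summary(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, size=(30, 3)), rng.normal(4, 1, size=(30, 3))])
        import pandas as pd

        df = pd.DataFrame(X, columns=["f1", "f2", "f3"])
        df["class"] = ["a"] * 30 + ["b"] * 30
        model = npc.PSNClassificationModel.from_dataframe(df, n_folds=5)
        results = model.fit(seed=0)
        text = results.summary()
        assert "Accuracy" in text and "MCC" in text
        assert 0 <= results.accuracy_mean <= 100
        assert results.per_fold().shape[0] == 5
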