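"""CART trees, random forests, importances and the reference cascade."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import accuracy
from glycoshift.encoding import N_DESCRIPTORS
from glycoshift.records import TASKS, labels_frame
from glycoshift.simulate import default_increment_model, generate_dataset
from glycoshift.trees import (
    apply_reference_tree,
    best_split,
    gini_impurity,
    importance,
    oob_report,
    proximity,
    rules_text,
    train_cart,
    train_rf,
)


def exhaustive_best_split(X, y):
    """Independent oracle: enumerate every descriptor and midpoint.

    Scores splits by the decrease in Gini impurity, with the library's
    declared tie rules (lowest descriptor index, then lowest threshold).
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    m = len(y)
    if m < 2:
        return None
    classes = sorted(set(y))

    def gini(labels):
        if not labels:
            return 0.0
        return 1.0 - sum((labels.count(c) / len(labels)) ** 2 for c in classes)

    parent = gini(y)
    best = None
    for j in range(X.shape[1]):
        values = sorted(set(X[:, j]))
        for lo, hi in zip(values, values[1:]):
            thr = (lo + hi) / 2.0
            left = [y[i] for i in range(m) if X[i, j] < thr]
            right = [y[i] for i in range(m) if X[i, j] >= thr]
            dec = parent - (len(left) * gini(left) + len(right) * gini(right)) / m
            if best is None or dec > best[2] + 1e-12:
                best = (j, thr, dec)
    if best is None or best[2] <= 1e-12:
        return None
    return best


def separable_data(n_per=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(40, 60, size=(2 * n_per, N_DESCRIPTORS))
    X[:n_per, 4] += 50.0
    y = ["A"] * n_per + ["B"] * n_per
    return X, y


class TestGini:
    def test_closed_forms(self):
        assert gini_impurity([10, 10]) == pytest.approx(0.5)
        assert gini_impurity([7, 0]) == 0.0
        assert gini_impurity([1, 1, 1, 1]) == pytest.approx(0.75)
        assert gini_impurity([2, 1]) == pytest.approx(1 - (4 + 1) / 9)

    def test_validation(self):
        with pytest.raises(ValueError):
            gini_impurity([-1, 2])
        with pytest.raises(ValueError):
            gini_impurity([0, 0])


class TestBestSplit:
    def test_perfect_split_at_midpoint(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        j, thr, dec = best_split(X, ["A", "A", "B", "B"])
        assert j == 0
        assert thr == pytest.approx(6.0)
        assert dec == pytest.approx(0.5)

    def test_constant_descriptors_return_none(self):
        X = np.full((6, 3), 7.0)
        assert best_split(X, ["A", "B", "A", "B", "A", "B"]) is None

    def test_single_object_returns_none(self):
        assert best_split(np.array([[1.0]]), ["A"]) is None

    def test_tie_prefers_lowest_descriptor_then_threshold(self):
        # two identical columns admit the same split: column 0 must win
        col = np.array([1.0, 2.0, 10.0, 11.0])
        X = np.column_stack([col, col])
        j, thr, _ = best_split(X, ["A", "A", "B", "B"])
        assert j == 0 and thr == pytest.approx(6.0)

    def test_candidate_restriction(self):
        col = np.array([1.0, 2.0, 10.0, 11.0])
        X = np.column_stack([col, col])
        j, _, _ = best_split(X, ["A", "A", "B", "B"], candidate_descriptors=[1])
        assert j == 1

    def test_pre_encoded_labels(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        enc = np.array([0, 0, 1, 1])
        assert best_split(X, enc, n_classes=2) == best_split(X, ["A", "A", "B", "B"])

    def test_matches_exhaustive_oracle_on_random_cases(self):
        rng = np.random.default_rng(14)
        for _ in range(40):
            n = int(rng.integers(2, 11))
            p = int(rng.integers(1, 5))
            X = np.round(rng.uniform(0, 10, size=(n, p)), 1)
            y = [str(v) for v in rng.integers(0, 3, size=n)]
            got = best_split(X, y)
            want = exhaustive_best_split(X, y)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1])
                assert got[2] == pytest.approx(want[2])


class TestTrainCART:
    def test_single_class_gives_root_leaf(self):
        X = np.random.default_rng(0).uniform(0, 100, size=(30, 5))
        m = train_cart(X, ["A"] * 30, classes=("A", "B"))
        assert m.max_depth() == 0
        assert m.internal_features() == []
        assert set(m.predict(X)) == {"A"}

    def test_infinite_complexity_collapses_to_root(self):
        X, y = separable_data()
        m = train_cart(X, y, complexity=float("inf"))
        assert m.max_depth() == 0

    def test_separable_data_single_split(self):
        X, y = separable_data()
        m = train_cart(X, y, seed=0)
        assert m.internal_features() == [4]
        assert accuracy(m.predict(X), y) == 1.0

    def test_recovers_nested_rule_structure(self):
        # Six constant-feature groups engineered so the greedy tree must
        # combine four distinct descriptors, one of them twice, to
        # separate the classes (the cascade-with-reuse shape).
        X, y = _cascade_fixture()
        m = train_cart(X, y, seed=0, classes=("A", "B"))
        feats = m.internal_features()
        named = sorted(f"C{j + 1}" for j in feats)
        assert len(feats) == 5
        assert named == ["C16", "C21", "C23", "C6", "C6"]
        assert m.max_depth() >= 4
        assert accuracy(m.predict(X), y) == 1.0

    def test_pruning_strength_reported(self):
        X, y = separable_data()
        m = train_cart(X, y, seed=0)
        assert m.alpha >= 0.0

    def test_serialization_round_trip(self):
        from glycoshift.trees import CARTModel

        X, y = _cascade_fixture()
        m = train_cart(X, y, seed=0, classes=("A", "B"))
        back = CARTModel.from_dict(m.to_dict())
        assert np.array_equal(back.predict(X), m.predict(X))
        assert back.alpha == m.alpha

    def test_rules_text_mentions_descriptors_and_units(self):
        X, y = separable_data()
        m = train_cart(X, y, seed=0)
        text = rules_text(m)
        assert "if C5 < " in text and "ppm" in text and "predict" in text


def _cascade_fixture():
    rows, ys = [], []

    def group(n, label, overrides):
        base = {i: 100.0 for i in range(N_DESCRIPTORS)}
        base.update({15: 75.0, 5: 60.0, 20: 90.0, 22: 170.0})
        base.update(overrides)
        row = np.array([base[i] for i in range(N_DESCRIPTORS)])
        for _ in range(n):
            rows.append(row.copy())
            ys.append(label)

    group(32, "A", {15: 70.0})              # early-eluting C16 group
    group(20, "B", {})                       # hexose side, low C6 window
    group(20, "A", {5: 80.0})                # hexose side, high C6 window
    group(20, "B", {5: 40.0, 20: 99.0})      # deoxy side, high C21
    group(20, "B", {5: 40.0, 22: 176.0})     # deoxy side, carbonyl marker
    group(20, "A", {5: 40.0})                # deoxy side, remainder
    return np.array(rows), ys


class TestReferenceTree:
    def test_branch_examples(self):
        x = np.full(N_DESCRIPTORS, 100.0)
        x[15] = 70.0
        assert apply_reference_tree(x) == "A"
        x[15] = 80.0
        x[5] = 60.0
        assert apply_reference_tree(x) == "B"
        x[5] = 40.0
        x[20] = 99.0
        assert apply_reference_tree(x) == "B"
        x[20] = 90.0
        x[22] = 176.0
        assert apply_reference_tree(x) == "B"
        x[22] = 170.0
        assert apply_reference_tree(x) == "A"

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            apply_reference_tree(np.zeros(5))


class TestRandomForest:
    def test_determinism_and_perfect_separable_fit(self):
        X, y = separable_data()
        a = train_rf(X, y, n_trees=25, seed=3)
        b = train_rf(X, y, n_trees=25, seed=3)
        assert np.array_equal(a.bootstrap_indices, b.bootstrap_indices)
        assert np.array_equal(a.predict(X), b.predict(X))
        assert accuracy(a.predict(X), y) == 1.0

    def test_vote_proba_rows_sum_to_one(self):
        X, y = separable_data()
        m = train_rf(X, y, n_trees=15, seed=1)
        proba = m.vote_proba(X[:10])
        assert proba.shape == (10, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_bootstrap_oob_fraction_near_e_inverse(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 100, size=(200, N_DESCRIPTORS))
        y = ["A" if v < 50 else "B" for v in X[:, 0]]
        m = train_rf(X, y, n_trees=50, seed=2)
        fractions = [
            1 - len(set(int(i) for i in bag)) / 200 for bag in m.bootstrap_indices
        ]
        assert np.mean(fractions) == pytest.approx((1 - 1 / 200) ** 200, abs=0.02)

    def test_oob_report_probabilities_and_coverage(self):
        X, y = separable_data()
        m = train_rf(X, y, n_trees=60, seed=4)
        report, proba = oob_report(m, X, y)
        assert sum(report.sizes) == len(y)
        assert np.allclose(np.nansum(proba, axis=1), 1.0)
        assert report.mean_predictability >= 95.0

    def test_oob_report_warns_when_objects_never_leave_the_bag(self):
        X, y = separable_data(n_per=20)
        m = train_rf(X, y, n_trees=1, seed=0)
        with pytest.warns(UserWarning, match="in-bag for every tree"):
            report, proba = oob_report(m, X, y)
        assert sum(report.sizes) < len(y)

    def test_too_few_objects_raise(self):
        with pytest.raises(ValueError):
            train_rf(np.ones((1, 3)), ["A"])

    def test_serialization_round_trip(self):
        from glycoshift.trees import ForestModel

        X, y = separable_data(n_per=15)
        m = train_rf(X, y, n_trees=10, seed=6)
        back = ForestModel.from_dict(m.to_dict())
        assert np.array_equal(back.predict(X), m.predict(X))


class TestImportance:
    def test_unused_constant_descriptor_scores_zero_gini(self):
        X, y = separable_data()
        X[:, 7] = 55.5  # constant: can never be split on
        m = train_rf(X, y, n_trees=40, seed=5)
        report = importance(m, X, y, seed=5)
        assert report.mean_decrease_gini[7] == 0.0
        assert report.mean_decrease_gini[4] > 0.0

    def test_determinism_and_ranking_names(self):
        X, y = separable_data(n_per=20)
        m = train_rf(X, y, n_trees=30, seed=8)
        a = importance(m, X, y, seed=8)
        b = importance(m, X, y, seed=8)
        assert np.array_equal(a.mean_decrease_accuracy, b.mean_decrease_accuracy)
        assert a.ranking("gini")[0] == "C5"
        assert a.top(3, "accuracy")[0] == "C5"
        assert len(a.top(10)) == 10


class TestProximity:
    def test_properties(self):
        X, y = separable_data(n_per=15)
        m = train_rf(X, y, n_trees=20, seed=9)
        sim = proximity(m, X[np.r_[0:6, 15:21]])  # six objects per class
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim, sim.T)
        assert sim.min() >= 0.0 and sim.max() <= 1.0
        # objects of the same separable class co-occur more often
        assert sim[:6, :6].mean() > sim[:6, 6:].mean()


class TestAgainstSklearn:
    def test_oob_accuracy_matches_independent_forest(self, default_matrix, default_labels):
        from sklearn.ensemble import RandomForestClassifier

        X, _ = default_matrix
        for task in ("ano_r", "s_link"):
            y = list(default_labels[task])
            m = train_rf(X, y, n_trees=500, seed=7, classes=TASKS[task], task=task)
            report, _ = oob_report(m, X, y)
            pkg = sum(report.correct) / sum(report.sizes)
            sk = RandomForestClassifier(
                n_estimators=500, max_features=4, oob_score=True, random_state=7
            )
            sk.fit(X, y)
            assert abs(pkg - sk.oob_score_) < 0.05, task
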