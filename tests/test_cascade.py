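"""Classifier cascade: splits, grid, C-index, Shapley ranking, routing."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from protriage import (
    GeneratorConfig,
    SplitSpec,
    c_index,
    cascade_predict,
    default_grid,
    evaluate_cascade,
    grid_search,
    shap_rank,
    simulate_cohort,
    split_data,
    train_cascade,
)
from protriage.cascade import LABEL_THERAPY, expand_grid, select_subset
from protriage.shapley import _leaf_values, tree_shap_values

SMALL_GRID = {"n_estimators": [50, 100], "max_depth": [4], "min_samples_leaf": [1, 3]}


class TestSplit:
    def test_sixty_twenty_twenty(self):
        y = np.repeat([0, 1], 50)
        tr, va, te = split_data(y, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (60, 20, 20)
        # disjoint and exhaustive
        assert sorted(np.concatenate([tr, va, te])) == list(range(100))

    def test_reproducible_and_stratified(self):
        y = np.array([0] * 80 + [1] * 20)
        a = split_data(y, SplitSpec(seed=4))
        b = split_data(y, SplitSpec(seed=4))
        for x, z in zip(a, b):
            np.testing.assert_array_equal(x, z)
        for part in a:
            assert 0 < y[part].mean() < 1  # both classes everywhere

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            split_data(np.array([0, 1] * 4), SplitSpec(seed=0))


class TestGrid:
    def test_default_grid_has_150_combinations(self):
        assert len(expand_grid(default_grid())) == 150

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            expand_grid({"n_estimators": [], "max_depth": [2], "min_samples_leaf": [1]})

    def test_singleton_grid_returns_that_combination(self, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] > 0).astype(int)
        combo = {"n_estimators": [10], "max_depth": [3], "min_samples_leaf": [1]}
        best = grid_search(X[:40], y[:40], X[40:], y[40:], combo, seed=0)
        assert best == {"n_estimators": 10, "max_depth": 3, "min_samples_leaf": 1}

    def test_strong_signal_reaches_high_validation_c_index(self, rng):
        n = 400
        X = rng.normal(size=(n, 10))
        y = rng.integers(0, 2, n)
        X[:, 3] += 4.0 * y
        best = grid_search(X[:300], y[:300], X[300:], y[300:], SMALL_GRID, seed=0)
        model = RandomForestClassifier(random_state=0, **best).fit(X[:300], y[:300])
        assert c_index(model.predict_proba(X[300:])[:, 1], y[300:]) >= 0.95


def brute_force_c_index(scores, labels):
    scores = [Fraction(s).limit_denominator(10**9) for s in scores]
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = Fraction(0)
    for p in pos:
        for q in neg:
            num += 1 if p > q else (Fraction(1, 2) if p == q else 0)
    return num / (len(pos) * len(neg))


class TestCIndex:
    def test_perfect_separation(self):
        assert c_index([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert c_index([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_worked_four_pair_enumeration(self):
        assert c_index([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == pytest.approx(3 / 4)

    def test_matches_exact_rational_oracle_on_200_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.normal(size=n), 2)  # rounding makes ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            expected = brute_force_c_index(scores.tolist(), labels.tolist())
            assert c_index(scores, labels) == pytest.approx(float(expected), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_index([0.1, 0.2], [1, 1])


def brute_force_shap(model, x, n_features):
    """Shapley values of the tree's cover-weighted conditional expectation."""
    def expvalue(tree, leafval, subset):
        def rec(j):
            if tree.children_left[j] < 0:
                return leafval[j]
            d = tree.feature[j]
            left, right = tree.children_left[j], tree.children_right[j]
            if d in subset:
                return rec(left) if x[d] <= tree.threshold[j] else rec(right)
            wl = tree.weighted_n_node_samples[left]
            wr = tree.weighted_n_node_samples[right]
            return (wl * rec(left) + wr * rec(right)) / (wl + wr)
        return rec(0)

    phi = np.zeros(n_features)
    estimators = getattr(model, "estimators_", [model])
    for est in estimators:
        tree, leafval = est.tree_, _leaf_values(est.tree_)
        for i in range(n_features):
            others = [f for f in range(n_features) if f != i]
            for k in range(n_features):
                for subset in itertools.combinations(others, k):
                    w = (math.factorial(k) * math.factorial(n_features - k - 1)
                         / math.factorial(n_features))
                    phi[i] += w * (expvalue(tree, leafval, set(subset) | {i})
                                   - expvalue(tree, leafval, set(subset)))
    return phi / len(estimators)


class TestShapley:
    def test_additivity_identity_on_random_samples(self, rng):
        X = rng.normal(size=(150, 6))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.3, 150) > 0).astype(int)
        model = RandomForestClassifier(n_estimators=30, max_depth=6,
                                       random_state=0).fit(X, y)
        Xq = rng.normal(size=(50, 6))
        phi, base = tree_shap_values(model, Xq)
        np.testing.assert_allclose(phi.sum(axis=1) + base,
                                   model.predict_proba(Xq)[:, 1], atol=1e-6)

    def test_matches_brute_force_subset_enumeration(self, rng):
        X = rng.normal(size=(80, 4))
        y = X[:, 0] * 2 + np.sin(3 * X[:, 1]) + rng.normal(0, 0.1, 80)
        model = RandomForestRegressor(n_estimators=5, max_depth=5,
                                      random_state=1).fit(X, y)
        for _ in range(4):
            xq = rng.normal(size=4)
            phi, _ = tree_shap_values(model, xq[None, :])
            np.testing.assert_allclose(phi[0], brute_force_shap(model, xq, 4),
                                       atol=1e-10)

    def test_single_feature_model_ranks_it_first(self, rng):
        X = rng.normal(size=(200, 5))
        y = (X[:, 2] > 0).astype(int)
        model = RandomForestClassifier(n_estimators=20, max_depth=3,
                                       random_state=0).fit(X, y)
        ranking = shap_rank(model, X, [f"f{i}" for i in range(5)])
        assert ranking.index[0] == "f2"
        assert ranking.iloc[0] > 10 * ranking.iloc[1]

    def test_duplicated_feature_attribution_is_conserved(self, rng):
        # bootstrap off and all features considered: both forests learn the
        # same function of feature 0, so the copies must share its credit
        X = rng.normal(size=(300, 3))
        y = (X[:, 0] > 0).astype(int)
        kwargs = dict(n_estimators=30, random_state=0, max_depth=4,
                      bootstrap=False, max_features=None)
        single = RandomForestClassifier(**kwargs).fit(X, y)
        Xd = np.column_stack([X, X[:, 0]])  # perfect copy of feature 0
        dup = RandomForestClassifier(**kwargs).fit(Xd, y)
        phi_s, _ = tree_shap_values(single, X[:100])
        phi_d, _ = tree_shap_values(dup, Xd[:100])
        np.testing.assert_allclose(phi_d[:, 0] + phi_d[:, 3], phi_s[:, 0], atol=1e-8)
        np.testing.assert_allclose(phi_d[:, 1:3], phi_s[:, 1:3], atol=1e-8)


class TestSubsetSelection:
    def test_planted_singleton_wins_and_63_subsets(self, rng):
        n = 300
        X = rng.normal(size=(n, 8))
        y = rng.integers(0, 2, n)
        X[:, 5] += 6.0 * y  # only informative column
        cols = [f"p{i}" for i in range(8)]
        ranked = ["p5"] + [c for c in cols if c != "p5"]
        params = {"n_estimators": 50, "max_depth": 4, "min_samples_leaf": 1}
        stage = select_subset(X[:180], y[:180], X[180:240], y[180:240],
                              X[240:], y[240:], ranked, cols, params, seed=0,
                              stage=1, positive_clusters=("C1",))
        assert stage.selected_proteins == ["p5"]
        assert stage.validation_c_index >= 0.95
        assert 1 <= len(stage.selected_proteins) <= 6
        assert sum(1 for size in range(1, 7)
                   for _ in itertools.combinations(range(6), size)) == 63


@pytest.fixture(scope="module")
def trained():
    cohort = simulate_cohort(
        GeneratorConfig(n_patients=500, n_proteins=60, frac_marker_proteins=0.5,
                        signature_effect=4.0, seed=8)
    )
    cascade, splits = train_cascade(cohort.expression, cohort.true_cluster,
                                    SplitSpec(seed=8), SMALL_GRID)
    return cohort, cascade, splits


class TestCascade:
    def test_training_is_deterministic(self, trained):
        cohort, cascade, _ = trained
        again, _ = train_cascade(cohort.expression, cohort.true_cluster,
                                 SplitSpec(seed=8), SMALL_GRID)
        for s in (1, 2, 3):
            assert cascade.stages[s].selected_proteins == again.stages[s].selected_proteins
            assert cascade.stages[s].hyperparameters == again.stages[s].hyperparameters
            assert cascade.stages[s].validation_c_index == again.stages[s].validation_c_index

    def test_routing_precedence_and_batch_statelessness(self, trained):
        cohort, cascade, _ = trained
        preds = cascade_predict(cohort.expression, cascade)
        stage1_pos = preds["stage1_score"] >= cascade.threshold
        assert (preds.loc[stage1_pos, "recommendation"] == "VH").all()
        # batch prediction equals the map of single predictions
        for pid in cohort.expression.index[:5]:
            single = cascade_predict(cohort.expression.loc[[pid]], cascade)
            assert single["recommendation"].iloc[0] == preds.loc[pid, "recommendation"]

    def test_missing_protein_named_in_error(self, trained):
        cohort, cascade, _ = trained
        needed = cascade.stages[1].selected_proteins[0]
        with pytest.raises(KeyError, match=needed):
            cascade_predict(cohort.expression.drop(columns=[needed]), cascade)

    def test_held_out_metrics_and_confusion(self, trained):
        cohort, cascade, splits = trained
        test_ids = splits[1]["test"]
        metrics = evaluate_cascade(cohort.expression.loc[test_ids],
                                   cohort.true_cluster.loc[test_ids], cascade)
        assert metrics["correct_therapy_fraction"] >= 0.8
        assert metrics["misassigned_fraction"] <= 0.2
        assert metrics["confusion"].to_numpy().sum() == len(test_ids)

    def test_oracle_scores_give_perfect_therapy_assignment(self):
        # hand-built cascade scores that mirror the labels exactly
        labels = pd.Series(["C1", "C2", "C3", "C4", "C5"] * 4,
                           index=[f"P{i}" for i in range(20)])
        s1 = (labels == "C1").astype(float)
        s2 = labels.isin(["C2", "C4"]).astype(float)
        s3 = (labels == "C3").astype(float)
        rec = np.where(s1 >= 0.5, "VH",
                       np.where(s2 >= 0.5, "CC", np.where(s3 >= 0.5, "CC_INTENSIFY", "NEITHER")))
        implied = labels.map(LABEL_THERAPY)
        arm = lambda t: "CC" if t == "CC_INTENSIFY" else t
        assert (pd.Series(rec, index=labels.index).map(arm) == implied.map(arm)).all()
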