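import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from weanwave.predict import (
    ForestReport,
    ForestSpec,
    TreeStructure,
    bootstrap_eval,
    feature_importance,
    fit_forest,
    gini,
    metrics,
    node_importances,
    rsbi_rule,
)

from .oracles import recursive_node_importances, tree_feature_importance


class TestGini:
    @pytest.mark.parametrize(
        "probs,expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), 0.5), ((0.75, 0.25), 0.375)],
    )
    def test_closed_forms(self, probs, expected):
        assert gini(probs) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("probs", [(0.5, 0.6), (-0.1, 1.1), ()])
    def test_malformed_vector_errors(self, probs):
        with pytest.raises(ValueError):
            gini(probs)


def toy_data(n=40, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    if separable:
        y = np.where(X[:, 0] > 0, "success", "failure")
    else:
        y = np.array(["success", "failure"])[rng.integers(0, 2, n)]
    return pd.DataFrame(X, columns=["f0", "f1"]), y


class TestFitForest:
    def test_separable_training_accuracy(self):
        X, y = toy_data(separable=True)
        report = fit_forest(X, y, ForestSpec(seed=1))
        assert (report.predict(X.to_numpy()) == y).mean() == 1.0

    def test_prediction_is_majority_of_tree_votes(self):
        X, y = toy_data(n=30, seed=3, separable=False)
        report = fit_forest(X, y, ForestSpec(seed=2))
        Xt = X.to_numpy()[:10]
        preds = report.predict(Xt)
        for i in range(10):
            votes = Counter(
                int(est.predict(Xt[i : i + 1])[0])
                for est in report._sk_model.estimators_
            )
            expected = "success" if votes[1] >= votes[0] else "failure"
            assert preds[i] == expected

    def test_same_seed_same_report(self):
        X, y = toy_data(seed=5, separable=False)
        r1 = fit_forest(X, y, ForestSpec(seed=9))
        r2 = fit_forest(X, y, ForestSpec(seed=9))
        assert feature_importance(r1).equals(feature_importance(r2))
        assert np.array_equal(
            r1.predict_proba_success(X.to_numpy()),
            r2.predict_proba_success(X.to_numpy()),
        )

    def test_leaf_probabilities_are_probabilities(self):
        X, y = toy_data(seed=5, separable=False)
        report = fit_forest(X, y, ForestSpec(seed=9))
        for tree in report.trees:
            leaves = tree.leaf_success_prob[~np.isnan(tree.leaf_success_prob)]
            assert np.all((leaves >= 0) & (leaves <= 1))
            assert tree.n_leaves == len(leaves)

    def test_single_class_errors(self):
        X, _ = toy_data()
        with pytest.raises(ValueError, match="both classes"):
            fit_forest(X, ["success"] * len(X), ForestSpec(seed=0))

    def test_nan_features_error(self):
        X, y = toy_data()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_forest(X, y, ForestSpec(seed=0))


def manual_depth2_tree():
    """Hand-built 5-node tree with known weights and impurities.

    Root (w=1, G=0.5) splits on feature 0 into an impure left child
    (w=0.6, G=1/3) and a pure right child (w=0.4, G=0); the left child
    splits on feature 1 into two pure leaves (w=0.4 and w=0.2).
    """
    return TreeStructure(
        feature=np.array([0, 1, -2, -2, -2]),
        children_left=np.array([1, 3, -1, -1, -1]),
        children_right=np.array([2, 4, -1, -1, -1]),
        impurity=np.array([0.5, 1.0 / 3.0, 0.0, 0.0, 0.0]),
        weight=np.array([1.0, 0.6, 0.4, 0.4, 0.2]),
        leaf_success_prob=np.array([np.nan, np.nan, 1.0, 0.0, 1.0]),
    )


class TestFeatureImportance:
    def test_hand_computed_depth2_tree(self):
        tree = manual_depth2_tree()
        ni = node_importances(tree)
        # ni_root = 1*0.5 - 0.6*(1/3) - 0.4*0 = 0.3 ; ni_left = 0.6*(1/3) = 0.2
        assert ni[0] == pytest.approx(0.3, abs=1e-12)
        assert ni[1] == pytest.approx(0.2, abs=1e-12)
        report = ForestReport(
            spec=ForestSpec(), feature_names=("f0", "f1"),
            classes=("failure", "success"), trees=[tree],
        )
        fi = feature_importance(report)
        assert fi["f0"] == pytest.approx(0.6, abs=1e-12)
        assert fi["f1"] == pytest.approx(0.4, abs=1e-12)

    def test_single_split_gets_full_importance(self):
        X = pd.DataFrame({"f0": [0.0, 1.0, 0.0, 1.0], "f1": [5.0, 5.0, 5.0, 5.0]})
        y = np.array(["failure", "success", "failure", "success"])
        report = fit_forest(X, y, ForestSpec(n_estimators=5, seed=0))
        fi = feature_importance(report)
        assert fi["f0"] == pytest.approx(1.0)
        assert fi["f1"] == 0.0

    def test_matches_recursive_traversal_oracle(self):
        X, y = toy_data(n=12, seed=8, separable=False)
        report = fit_forest(X, y, ForestSpec(n_estimators=10, seed=4))
        checked = 0
        for tree in report.trees:
            ni_fast = node_importances(tree)
            ni_slow = recursive_node_importances(tree)
            for j, v in ni_slow.items():
                assert ni_fast[j] == pytest.approx(v, abs=1e-12)
            total = ni_fast.sum()
            if total == 0:  # stump (bootstrap sample was single-class)
                continue
            fi_slow = tree_feature_importance(tree, 2)
            internal = tree.feature >= 0
            fi_fast = np.zeros(2)
            np.add.at(fi_fast, tree.feature[internal], ni_fast[internal])
            assert np.allclose(fi_fast / total, fi_slow, atol=1e-12)
            checked += 1
        assert checked > 0

    def test_agrees_with_sklearn_importances(self):
        X, y = toy_data(n=60, seed=2, separable=False)
        report = fit_forest(X, y, ForestSpec(seed=7))
        ours = feature_importance(report).to_numpy()
        theirs = report._sk_model.feature_importances_
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_normalisation(self):
        X, y = toy_data(n=50, seed=1, separable=False)
        fi = feature_importance(fit_forest(X, y, ForestSpec(seed=3)))
        assert fi.sum() == pytest.approx(1.0, abs=1e-9)
        assert (fi >= 0).all()


class TestRsbiRule:
    @pytest.mark.parametrize(
        "value,expected",
        [(104.9, "success"), (105.0, "failure"), (40.0, "success")],
    )
    def test_threshold(self, value, expected):
        assert rsbi_rule(value) == expected

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            rsbi_rule(0.0)


class TestMetrics:
    def test_confusion_arithmetic(self):
        labels = ["success"] * 10 + ["failure"] * 10
        preds = (
            ["success"] * 9 + ["failure"]          # TP=9, FN=1
            + ["failure"] * 8 + ["success"] * 2    # TN=8, FP=2
        )
        m = metrics(labels, preds)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)

    def test_auroc_equals_rank_sum_identity(self, rng):
        labels = np.where(rng.uniform(size=200) < 0.3, "success", "failure")
        scores = rng.normal(size=200) + (labels == "success")
        m = metrics(labels, labels, scores)  # predictions irrelevant to AUROC
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(
            scores[labels == "success"], scores[labels == "failure"]
        ).statistic
        n1 = (labels == "success").sum()
        n2 = (labels == "failure").sum()
        assert m["auroc"] == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_perfect_classifier(self):
        labels = ["success"] * 5 + ["failure"] * 5
        scores = [1.0] * 5 + [0.0] * 5
        m = metrics(labels, labels, scores)
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv",
                     "f1_success", "f1_failure", "auroc"):
            assert m[name] == 1.0

    def test_order_invariance(self, rng):
        labels = np.array(["success"] * 12 + ["failure"] * 8)
        preds = labels.copy()
        preds[[0, 15]] = ["failure", "success"]
        scores = rng.normal(size=20)
        m1 = metrics(labels, preds, scores)
        perm = rng.permutation(20)
        m2 = metrics(labels[perm], preds[perm], scores[perm])
        for k, v in m1.items():
            assert m2[k] == pytest.approx(v, abs=1e-12)

    def test_single_class_auroc_undefined(self):
        m = metrics(["success"] * 5, ["success"] * 5, [1, 2, 3, 4, 5])
        assert math.isnan(m["auroc"])


def feature_table(n_success=20, n_failure=12, effect=1.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = ["success"] * n_success + ["failure"] * n_failure
    shift = np.r_[np.zeros(n_success), np.full(n_failure, effect)]
    return pd.DataFrame(
        {
            "label": labels,
            "biomarker": rng.normal(size=len(labels)) + shift,
            "rsbi": rng.normal(60, 15, len(labels)).clip(10)
            + 10 * (np.asarray(labels) == "failure") * effect,
        }
    )


class TestBootstrapEval:
    def test_perfect_separation_degenerate_ci(self):
        table = feature_table(effect=0.0)
        table["biomarker"] = np.where(table["label"] == "success", 1.0, 0.0)
        rep = bootstrap_eval(
            table, ["biomarker", "rsbi"], comparators=("forest",),
            n_iter=30, seed=1,
        )
        mean, lo, hi = rep.summary["forest"]["auroc"]
        assert mean == 1.0 and lo == 1.0 and hi == 1.0

    def test_label_permutation_yields_chance_auroc(self):
        # a single permuted cohort keeps a spurious association of order
        # sd(U)/n1n2 ~ 0.074 at these sizes, so chance behaviour is
        # assessed as the mean over permutations (8 draws -> SE ~ 0.026)
        table = feature_table(n_success=40, n_failure=25, effect=2.0, seed=3)
        rng = np.random.default_rng(4)
        means = []
        for _ in range(8):
            permuted = table.copy()
            permuted["label"] = rng.permutation(table["label"].to_numpy())
            rep = bootstrap_eval(
                permuted, ["biomarker", "rsbi"], comparators=("forest",),
                n_iter=50, seed=5,
            )
            means.append(rep.summary["forest"]["auroc"][0])
        assert np.mean(means) == pytest.approx(0.5, abs=0.08)

    def test_comparator_list_respected(self):
        table = feature_table()
        rep = bootstrap_eval(table, ["biomarker", "rsbi"],
                             comparators=("rsbi",), n_iter=10, seed=0)
        assert list(rep.summary) == ["rsbi"]

    def test_deterministic_under_seed(self):
        table = feature_table()
        kwargs = dict(n_iter=15, seed=11, comparators=("rsbi", "forest", "logistic"))
        r1 = bootstrap_eval(table, ["biomarker", "rsbi"], **kwargs)
        r2 = bootstrap_eval(table, ["biomarker", "rsbi"], **kwargs)
        assert r1.to_json() == r2.to_json()

    def test_ci_brackets_mean(self):
        table = feature_table(effect=1.5, seed=6)
        rep = bootstrap_eval(table, ["biomarker", "rsbi"], n_iter=50, seed=2)
        for comp in rep.summary.values():
            for mean, lo, hi in comp.values():
                if not math.isnan(mean):
                    assert lo <= mean <= hi

    def test_too_few_patients_errors(self):
        table = feature_table(n_success=4, n_failure=3)
        with pytest.raises(ValueError, match="at least 5"):
            bootstrap_eval(table, ["biomarker", "rsbi"], n_iter=5, seed=0)

    def test_single_split_mode_runs(self):
        table = feature_table(effect=1.0, seed=9)
        rep = bootstrap_eval(
            table, ["biomarker", "rsbi"], comparators=("forest",),
            n_iter=40, seed=3, mode="single_split",
        )
        assert rep.n_iterations == 40
        assert 0.0 <= rep.summary["forest"]["auroc"][0] <= 1.0
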