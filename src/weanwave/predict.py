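"""Weaning-success prediction and bootstrap performance evaluation.

Three comparators are evaluated on the per-patient feature table:

* **RSBI rule** — the bedside convention: RSBI below 105 breaths/min/L
  predicts weaning success, at or above 105 predicts failure.  Its
  ranking score for AUROC is the negated RSBI.
* **Random Forest** on the selected biosignal features plus RSBI, with
  the study hyperparameters (50 trees, Gini impurity, min samples per
  leaf 1, min samples to split 2).  Tree construction is delegated to
  scikit-learn, but the aggregate prediction (majority of per-tree
  votes) and the impurity-based feature importances — node importance
  ``ni_j = w_j G_j - w_left G_left - w_right G_right``, per-tree feature
  importance ``fi_i = sum(ni over nodes splitting on i) / sum(ni)``,
  averaged over trees — are computed by this module from the exported
  tree structures.
* **Multiple logistic regression** — main effects only, no
  regularisation, on the same inputs.

Performance (sensitivity, specificity, accuracy, PPV, NPV, F1, AUROC,
with weaning *success* as the positive class; F1 additionally reported
for the failure class) is summarised over repeated stratified 7:3
train/test splits — 1000 iterations by default — as the mean and the
2.5/97.5 percentile confidence interval per metric.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "RSBI_THRESHOLD",
    "ForestSpec",
    "ForestReport",
    "EvalReport",
    "gini",
    "fit_forest",
    "feature_importance",
    "rsbi_rule",
    "metrics",
    "bootstrap_eval",
    "METRIC_NAMES",
]

RSBI_THRESHOLD = 105.0
POSITIVE_LABEL = "success"
METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "accuracy",
    "ppv",
    "npv",
    "f1_success",
    "f1_failure",
    "auroc",
)


# ---------------------------------------------------------------------------
# Gini impurity
# ---------------------------------------------------------------------------

def gini(class_probs) -> float:
    """Gini impurity ``G = sum_i p(i) (1 - p(i))`` of a probability vector."""
    p = np.asarray(class_probs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("class_probs must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must be probabilities summing to 1")
    return float(np.sum(p * (1.0 - p)))


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestSpec:
    """Random-forest hyperparameters (defaults: the study settings)."""

    n_estimators: int = 50
    split_criterion: str = "gini"
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    seed: int | None = None


@dataclass
class TreeStructure:
    """Flat arrays describing one fitted tree (indices are node ids)."""

    feature: np.ndarray        # split feature per node; -2 marks a leaf
    children_left: np.ndarray
    children_right: np.ndarray
    impurity: np.ndarray       # Gini impurity G_j per node
    weight: np.ndarray         # w_j = N_j / N (training-sample fraction)
    leaf_success_prob: np.ndarray  # pi_{t,i} per node (NaN for internal)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))


@dataclass
class ForestReport:
    """Fitted forest plus the exported structure needed for importances."""

    spec: ForestSpec
    feature_names: tuple
    classes: tuple
    trees: list = field(repr=False, default_factory=list)
    _sk_model: RandomForestClassifier | None = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        """Majority of per-tree votes (ties broken toward success)."""
        X = np.asarray(X, dtype=float)
        votes = np.stack([est.predict(X) for est in self._sk_model.estimators_])
        pos = self._sk_model.classes_.tolist().index(1)
        frac = (votes == self._sk_model.classes_[pos]).mean(axis=0)
        return np.where(frac >= 0.5, POSITIVE_LABEL, "failure")

    def predict_proba_success(self, X) -> np.ndarray:
        """Mean per-tree leaf probability of success (AUROC score)."""
        X = np.asarray(X, dtype=float)
        pos = self._sk_model.classes_.tolist().index(1)
        return self._sk_model.predict_proba(X)[:, pos]


def _labels_to_int(labels) -> np.ndarray:
    y = np.asarray(labels)
    out = np.where(y == POSITIVE_LABEL, 1, 0)
    if set(np.unique(y)) - {"success", "failure"}:
        raise ValueError("labels must be 'success' or 'failure'")
    return out


def fit_forest(features, labels, spec: ForestSpec = ForestSpec()) -> ForestReport:
    """Train the forest and export per-tree structure for importance math.

    ``features`` may be a DataFrame (column names are kept) or an array.
    Training data must contain both classes and no NaN (impute first).
    Deterministic for a fixed ``spec.seed``.
    """
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    if np.isnan(X).any():
        raise ValueError("features contain NaN; impute before fitting")
    y = _labels_to_int(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    model = RandomForestClassifier(
        n_estimators=spec.n_estimators,
        criterion=spec.split_criterion,
        min_samples_leaf=spec.min_samples_leaf,
        min_samples_split=spec.min_samples_split,
        random_state=spec.seed,
    )
    model.fit(X, y)

    pos = model.classes_.tolist().index(1)
    trees = []
    for est in model.estimators_:
        t = est.tree_
        n_root = t.weighted_n_node_samples[0]
        counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
        probs = counts[:, pos] / counts.sum(axis=1)
        leaf_prob = np.where(t.children_left < 0, probs, np.nan)
        trees.append(
            TreeStructure(
                feature=t.feature.copy(),
                children_left=t.children_left.copy(),
                children_right=t.children_right.copy(),
                impurity=t.impurity.copy(),
                weight=t.weighted_n_node_samples / n_root,
                leaf_success_prob=leaf_prob,
            )
        )
    return ForestReport(
        spec=spec,
        feature_names=names,
        classes=("failure", POSITIVE_LABEL),
        trees=trees,
        _sk_model=model,
    )


def node_importances(tree: TreeStructure) -> np.ndarray:
    """``ni_j = w_j G_j - w_left G_left - w_right G_right`` per node.

    Leaves have no split and contribute 0.
    """
    ni = np.zeros(len(tree.feature))
    internal = tree.feature >= 0
    left = tree.children_left[internal]
    right = tree.children_right[internal]
    ni[internal] = (
        tree.weight[internal] * tree.impurity[internal]
        - tree.weight[left] * tree.impurity[left]
        - tree.weight[right] * tree.impurity[right]
    )
    return ni


def feature_importance(report: ForestReport):
    """Normalised impurity-based importances, averaged over trees.

    Per tree: ``fi_i = sum_{j splits on i} ni_j / sum_k ni_k``; the
    per-tree vectors (each summing to 1) are averaged over all trees and
    renormalised.  A forest in which no tree splits (all stumps) yields
    an all-zero result flagged by ``sum == 0``.
    """
    n_feat = len(report.feature_names)
    per_tree = []
    for tree in report.trees:
        ni = node_importances(tree)
        total = ni.sum()
        fi = np.zeros(n_feat)
        if total > 0:
            internal = tree.feature >= 0
            np.add.at(fi, tree.feature[internal], ni[internal])
            fi /= total
        per_tree.append(fi)
    avg = np.mean(per_tree, axis=0) if per_tree else np.zeros(n_feat)
    s = avg.sum()
    if s > 0:
        avg = avg / s
    return pd.Series(avg, index=list(report.feature_names), name="importance")


# ---------------------------------------------------------------------------
# RSBI rule and metrics
# ---------------------------------------------------------------------------

def rsbi_rule(rsbi_value):
    """Threshold rule: RSBI < 105 predicts success, >= 105 failure."""
    v = np.asarray(rsbi_value, dtype=float)
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("RSBI must be positive and finite")
    out = np.where(v < RSBI_THRESHOLD, POSITIVE_LABEL, "failure")
    return out.item() if out.ndim == 0 else out


def _auroc(scores, y) -> float:
    """AUROC by the rank (Mann-Whitney) formulation, midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return math.nan
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def metrics(labels, predictions, scores=None) -> dict:
    """Confusion-matrix metrics with weaning success as the positive class.

    F1 is reported for both classes (``f1_success`` and ``f1_failure``)
    because the two conventions answer different clinical questions at a
    75/25 prevalence.  ``scores`` (higher = more likely success) are
    required for AUROC; a single-class label vector leaves AUROC NaN.
    """
    y = _labels_to_int(labels)
    yhat = _labels_to_int(predictions)
    if len(y) != len(yhat):
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))

    def safe(num, den):
        return num / den if den > 0 else math.nan

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    ppv = safe(tp, tp + fp)
    npv = safe(tn, tn + fn)
    f1_pos = safe(2 * tp, 2 * tp + fp + fn)
    f1_neg = safe(2 * tn, 2 * tn + fn + fp)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": safe(tp + tn, len(y)),
        "ppv": ppv,
        "npv": npv,
        "f1_success": f1_pos,
        "f1_failure": f1_neg,
        "auroc": _auroc(scores, y) if scores is not None else math.nan,
    }
    return out


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Bootstrap metric summaries per comparator.

    ``summary`` maps comparator name to ``{metric: (mean, lo, hi)}``
    (2.5/97.5 percentile CI); ``distributions`` keeps the raw per-
    iteration metric arrays for plotting or further analysis.
    """

    summary: dict
    n_iterations: int
    train_frac: float
    seed: int
    n_redrawn: int = 0
    distributions: dict = field(repr=False, default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "n_iterations": self.n_iterations,
            "train_frac": self.train_frac,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "comparators": {
                name: {
                    metric: {"mean": m, "ci_low": lo, "ci_high": hi}
                    for metric, (m, lo, hi) in metric_map.items()
                }
                for name, metric_map in self.summary.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _stratified_split(y: np.ndarray, train_frac: float, rng):
    train_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
    train = np.sort(np.concatenate(train_idx))
    mask = np.zeros(len(y), dtype=bool)
    mask[train] = True
    return train, np.flatnonzero(~mask)


def _impute_median(train_X: pd.DataFrame, test_X: pd.DataFrame):
    med = train_X.median()
    med = med.fillna(0.0)
    return train_X.fillna(med), test_X.fillna(med)


def bootstrap_eval(
    table: pd.DataFrame,
    feature_names,
    comparators=("rsbi", "forest", "logistic"),
    n_iter: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
    forest_spec: ForestSpec = ForestSpec(),
    mode: str = "resplit",
) -> EvalReport:
    """Evaluate comparators over repeated stratified 7:3 splits.

    ``table`` needs a ``label`` column, an ``rsbi`` column and the model
    feature columns.  Each iteration draws a fresh stratified split,
    fits the trainable comparators on the training part (missing values
    imputed by training-split medians) and scores the held-out part;
    the report carries the per-metric mean and 2.5/97.5 percentile CI.
    ``mode='single_split'`` instead fixes one split and bootstraps the
    held-out predictions.  All randomness derives from ``seed``.
    """
    if mode not in ("resplit", "single_split"):
        raise ValueError(f"unknown mode {mode!r}")
    y_all = _labels_to_int(table["label"].to_numpy())
    if y_all.sum() < 5 or (len(y_all) - y_all.sum()) < 5:
        raise ValueError("need at least 5 patients per class")
    feature_names = [f for f in feature_names if f != "label"]
    X_all = table[feature_names].astype(float)
    rsbi_all = table["rsbi"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    results = {name: {m: [] for m in METRIC_NAMES} for name in comparators}
    n_redrawn = 0

    fixed_split = None
    if mode == "single_split":
        fixed_split = _stratified_split(y_all, train_frac, rng)

    for it in range(n_iter):
        if mode == "resplit":
            train, test = _stratified_split(y_all, train_frac, rng)
        else:
            train0, test0 = fixed_split
            # bootstrap the held-out set, redrawing single-class resamples
            while True:
                test = rng.choice(test0, size=len(test0), replace=True)
                if len(np.unique(y_all[test])) == 2:
                    break
                n_redrawn += 1
            train = train0
        labels_test = table["label"].to_numpy()[test]

        it_seed = int(rng.integers(0, 2**31 - 1))
        X_train, X_test = _impute_median(X_all.iloc[train], X_all.iloc[test])
        y_train = table["label"].to_numpy()[train]

        for name in comparators:
            if name == "rsbi":
                preds = rsbi_rule(np.clip(rsbi_all[test], 1e-6, None))
                scores = -rsbi_all[test]
            elif name == "forest":
                report = fit_forest(
                    X_train, y_train,
                    ForestSpec(
                        n_estimators=forest_spec.n_estimators,
                        split_criterion=forest_spec.split_criterion,
                        min_samples_leaf=forest_spec.min_samples_leaf,
                        min_samples_split=forest_spec.min_samples_split,
                        seed=it_seed,
                    ),
                )
                preds = report.predict(X_test.to_numpy())
                scores = report.predict_proba_success(X_test.to_numpy())
            elif name == "logistic":
                # C=inf disables the ridge penalty: plain maximum-likelihood
                # multiple logistic regression
                clf = make_pipeline(
                    StandardScaler(),
                    LogisticRegression(C=np.inf, max_iter=5000),
                )
                clf.fit(X_train.to_numpy(), _labels_to_int(y_train))
                proba = clf.predict_proba(X_test.to_numpy())[:, 1]
                preds = np.where(proba >= 0.5, POSITIVE_LABEL, "failure")
                scores = proba
            else:
                raise ValueError(f"unknown comparator {name!r}")
            mm = metrics(labels_test, preds, scores)
            for metric in METRIC_NAMES:
                results[name][metric].append(mm[metric])

    summary = {}
    distributions = {}
    for name in comparators:
        summary[name] = {}
        distributions[name] = {}
        for metric in METRIC_NAMES:
            arr = np.asarray(results[name][metric], dtype=float)
            distributions[name][metric] = arr
            valid = arr[~np.isnan(arr)]
            if valid.size:
                lo = float(np.percentile(valid, 2.5))
                hi = float(np.percentile(valid, 97.5))
                # guard against rounding placing the mean a ulp outside
                # a degenerate (constant-metric) interval
                mean = min(max(float(valid.mean()), lo), hi)
                summary[name][metric] = (mean, lo, hi)
            else:
                summary[name][metric] = (math.nan, math.nan, math.nan)

    return EvalReport(
        summary=summary,
        n_iterations=n_iter,
        train_frac=train_frac,
        seed=seed,
        n_redrawn=n_redrawn,
        distributions=distributions,
    )
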