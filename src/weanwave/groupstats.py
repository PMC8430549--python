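"""Two-group feature comparison with rank-indexed significance thresholds.

Each of the 34 variability features is compared between the weaning
success and failure groups with a two-sided Mann-Whitney U test.  To
control the false discovery rate over the ``m`` comparisons, the i-th
smallest p-value is assigned the threshold ``alpha_adj = alpha * i / m``
(``alpha = 0.1`` by default, chosen permissive to admit more candidate
predictors into the model).  The default decision rule is the literal
per-rank rule — feature ``i`` is significant iff ``p_(i) < alpha*i/m``
for *its own* rank — not the Benjamini–Hochberg step-up (which would
additionally accept everything below the largest passing rank); the
step-up is available as an optional mode.  A second, "near-significant"
tier (``p < 0.05`` by default, configurable, plus an optional explicit
include-list) marks features carried into the prediction model despite
failing the per-rank rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .variability import FEATURE_NAMES

__all__ = [
    "rank_sum_p",
    "rank_thresholds",
    "compare_groups",
    "ComparisonTable",
    "DEFAULT_ALPHA",
    "DEFAULT_NEAR_P",
]

DEFAULT_ALPHA = 0.1
DEFAULT_NEAR_P = 0.05

#: Combined sample size at or below which the exact null distribution is
#: enumerated (when there are no ties).
_EXACT_N = 12


def rank_sum_p(group_a, group_b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when the combined sample size is at most 12 and the
    data contain no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if a.size + b.size <= _EXACT_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.pvalue)


def rank_thresholds(pvalues, alpha: float = DEFAULT_ALPHA, *,
                    mode: str = "per_rank") -> pd.DataFrame:
    """Rank p-values and attach ``alpha_adj = alpha * i / m`` thresholds.

    Returns a DataFrame aligned with the input order, with columns
    ``p``, ``rank`` (1..m by ascending p, ties ranked by stable input
    order), ``alpha_adj`` (unrounded; round to 3 decimals for display)
    and ``significant``.  ``mode='per_rank'`` applies the literal rule
    ``p_(i) < alpha*i/m``; ``mode='step_up'`` the standard step-up.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if mode not in ("per_rank", "step_up"):
        raise ValueError(f"unknown mode {mode!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    alpha_adj = alpha * rank / m
    if mode == "per_rank":
        significant = p < alpha_adj
    else:
        sorted_p = p[order]
        passing = np.flatnonzero(sorted_p < alpha * np.arange(1, m + 1) / m)
        cutoff = passing.max() + 1 if passing.size else 0
        significant = np.zeros(m, dtype=bool)
        significant[order[:cutoff]] = True
    return pd.DataFrame(
        {"p": p, "rank": rank, "alpha_adj": alpha_adj, "significant": significant}
    )


@dataclass
class ComparisonTable:
    """Per-feature two-group comparison results.

    ``rows`` has one entry per *testable* feature with columns
    ``feature, success_mean, success_sd, failure_mean, failure_sd, p,
    rank, alpha_adj, significant, near_significant``; ``untestable``
    lists features excluded (fewer than two unmasked values in a group),
    which do not count toward ``m``.
    """

    rows: pd.DataFrame
    alpha: float
    m: int
    untestable: tuple = ()

    def selected_features(self, include_rsbi: bool = True) -> list:
        """Features carried into modelling: significant + near-significant."""
        sel = self.rows.loc[
            self.rows["significant"] | self.rows["near_significant"], "feature"
        ].tolist()
        if include_rsbi and "rsbi" not in sel:
            sel.append("rsbi")
        return sel

    def to_csv(self, path) -> None:
        out = self.rows.copy()
        out["alpha_adj"] = out["alpha_adj"].round(3)
        out["flag"] = np.where(
            out["significant"], "significant",
            np.where(out["near_significant"], "near_significant", ""),
        )
        out.to_csv(path, index=False)


def compare_groups(
    features: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    *,
    near_p: float = DEFAULT_NEAR_P,
    near_include: tuple = (),
    mode: str = "per_rank",
    feature_names=None,
) -> ComparisonTable:
    """Build the full comparison table from a per-patient feature table.

    ``features`` must contain a ``label`` column (``success``/``failure``)
    and one column per feature (NaN = masked).  Masked patients are
    dropped per feature; a feature left with fewer than two values in
    either group is flagged untestable and excluded from ``m`` before
    thresholds are computed.
    """
    if feature_names is None:
        feature_names = [c for c in features.columns
                         if c in FEATURE_NAMES or c == "rsbi"]
    succ = features[features["label"] == "success"]
    fail = features[features["label"] == "failure"]
    if succ.empty or fail.empty:
        raise ValueError("both outcome groups must be present")

    rows, untestable = [], []
    for name in feature_names:
        a = succ[name].dropna().to_numpy(dtype=float)
        b = fail[name].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            untestable.append(name)
            continue
        rows.append(
            {
                "feature": name,
                "success_mean": float(a.mean()),
                "success_sd": float(a.std(ddof=1)),
                "failure_mean": float(b.mean()),
                "failure_sd": float(b.std(ddof=1)),
                "p": rank_sum_p(a, b),
            }
        )
    if not rows:
        raise ValueError("no testable features")
    table = pd.DataFrame(rows)
    annot = rank_thresholds(table["p"].to_numpy(), alpha, mode=mode)
    table = pd.concat([table, annot.drop(columns="p")], axis=1)
    table["near_significant"] = ~table["significant"] & (
        (table["p"] < near_p) | table["feature"].isin(near_include)
    )
    return ComparisonTable(
        rows=table, alpha=alpha, m=len(table), untestable=tuple(untestable)
    )
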