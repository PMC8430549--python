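"""Independent brute-force oracles used only by the tests.

Each oracle is deliberately written in the most transparent way possible
(explicit loops / broadcasting, no shared code with the package) so the
fast implementations can be checked against them.
"""

import math

import numpy as np


def naive_sample_entropy(x, m=2, r=None, r_frac=0.2):
    """O(N^2) template-counting sample entropy (Chebyshev, <= r)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = r_frac * float(np.std(x))
    nt = n - m

    def count(length):
        templates = np.stack([x[i : i + length] for i in range(nt)])
        c = 0
        for i in range(nt):
            d = np.max(np.abs(templates[i + 1 :] - templates[i]), axis=1)
            c += int(np.sum(d <= r))
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.nan, a, b
    return -math.log(a / b), a, b


def rotated_poincare(x):
    """SD1/SD2 via explicit 45-degree rotation of the lagged point cloud."""
    x = np.asarray(x, dtype=float)
    pts = np.stack([x[:-1], x[1:]])  # (2, n-1)
    theta = np.pi / 4
    rot = np.array(
        [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
    )
    rotated = rot @ pts
    sd_along = float(np.std(rotated[0]))   # along identity line -> SD2
    sd_perp = float(np.std(rotated[1]))    # perpendicular -> SD1
    return sd_perp, sd_along


def recursive_node_importances(tree):
    """Recursive traversal computing ni_j = w_j G_j - w_l G_l - w_r G_r."""
    ni = {}

    def visit(j):
        left, right = int(tree.children_left[j]), int(tree.children_right[j])
        if left < 0:
            return
        ni[j] = (
            tree.weight[j] * tree.impurity[j]
            - tree.weight[left] * tree.impurity[left]
            - tree.weight[right] * tree.impurity[right]
        )
        visit(left)
        visit(right)

    visit(0)
    return ni


def tree_feature_importance(tree, n_features):
    """Per-tree normalised fi_i from the recursive node importances."""
    ni = recursive_node_importances(tree)
    fi = np.zeros(n_features)
    for j, value in ni.items():
        fi[int(tree.feature[j])] += value
    total = fi.sum()
    return fi / total if total > 0 else fi
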