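"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the code paths of the package implementation: the
contribution oracle enumerates every root-to-leaf path recursively and
follows split comparisons by hand; the AUC oracle counts concordant pairs.
"""

from __future__ import annotations

import numpy as np


def enumerate_paths(est):
    """All root-to-leaf paths of a fitted sklearn tree as lists of node ids."""
    tree = est.tree_
    paths = []

    def walk(node, prefix):
        prefix = prefix + [node]
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:
            paths.append(prefix)
            return
        walk(left, prefix)
        walk(right, prefix)

    walk(0, [])
    return paths


def _node_fraction(est, node):
    value = est.tree_.value[node].reshape(-1)
    total = value.sum()
    classes = list(est.classes_)
    if 1 not in classes:
        return 0.0
    return float(value[classes.index(1)] / (total if total > 0 else 1.0))


def brute_force_tree_contributions(est, x, n_features):
    """(bias, contributions) for one tree by path enumeration.

    The leaf is found by re-evaluating every split comparison along each
    enumerated path; the matching path's node-fraction deltas are credited
    to the parent's split feature.
    """
    tree = est.tree_
    for path in enumerate_paths(est):
        ok = True
        for parent, child in zip(path[:-1], path[1:]):
            feat, thr = tree.feature[parent], tree.threshold[parent]
            goes_left = x[feat] <= thr
            if goes_left != (tree.children_left[parent] == child):
                ok = False
                break
        if not ok:
            continue
        bias = _node_fraction(est, path[0])
        contrib = np.zeros(n_features)
        for parent, child in zip(path[:-1], path[1:]):
            contrib[tree.feature[parent]] += (
                _node_fraction(est, child) - _node_fraction(est, parent)
            )
        return bias, contrib
    raise AssertionError("no path matched; oracle is broken")


def brute_force_forest_contributions(model, x):
    """Average the per-tree oracle over all trees of a TrainedModel."""
    p = len(model.feature_names)
    biases, contribs = [], []
    for est in model.estimators:
        b, c = brute_force_tree_contributions(est, x, p)
        biases.append(b)
        contribs.append(c)
    return float(np.mean(biases)), np.mean(contribs, axis=0)


def mann_whitney_auc(scores, labels):
    """ROC AUC as the normalized count of concordant (pos, neg) pairs,
    ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * equal) / (len(pos) * len(neg))


def f1_sweep_oracle(scores, labels):
    """Exhaustive F1 sweep over observed thresholds (>= convention);
    smallest threshold among the maximizers."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best_t, best_f1 = None, -1.0
    for t in sorted(set(scores.tolist())):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = t, f1
    return best_t, best_f1
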