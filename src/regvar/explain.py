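"""Additive per-feature decomposition of forest scores.

Each tree's prediction for a variant is decomposed along its decision path:
the change in the node class-1-fraction estimate between a parent and the
child the variant descends into is credited to the feature the parent splits
on.  Summed over the path and averaged over trees this yields

    score = bias + sum_j contribution_j        (exactly),

where the bias is the mean root-node class-1 fraction.  For training
variants, only out-of-bag trees — trees whose balanced bootstrap did not
contain the variant — are used, so contributions are not overfit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.tree import DecisionTreeClassifier

from .model import TrainedModel

logger = logging.getLogger(__name__)


@dataclass
class ContributionVector:
    bias: float
    contributions: np.ndarray
    n_trees_used: int
    oob: bool
    variant_key: tuple | None = None

    @property
    def score(self) -> float:
        return float(self.bias + self.contributions.sum())


def _tree_arrays(est: DecisionTreeClassifier):
    """Per-node class-1 fraction, and the (node → feature, delta) map."""
    tree = est.tree_
    value = tree.value.reshape(tree.node_count, -1)
    # sklearn >= 1.3 stores class fractions; normalize defensively
    totals = value.sum(axis=1)
    col = {c: i for i, c in enumerate(est.classes_)}.get(1)
    if col is None:
        frac = np.zeros(tree.node_count)
    else:
        frac = value[:, col] / np.where(totals > 0, totals, 1.0)
    parent = np.full(tree.node_count, -1, dtype=np.int64)
    for node in range(tree.node_count):
        for child in (tree.children_left[node], tree.children_right[node]):
            if child != -1:
                parent[child] = node
    return frac, parent, tree.feature


def _tree_contribution_operator(est: DecisionTreeClassifier,
                                n_features: int) -> tuple[float, sparse.csr_matrix]:
    """Sparse (n_nodes × n_features) operator mapping a decision-path
    indicator to per-feature contributions, plus the root bias."""
    frac, parent, feature = _tree_arrays(est)
    n_nodes = len(frac)
    rows, cols, data = [], [], []
    for node in range(n_nodes):
        par = parent[node]
        if par == -1:
            continue
        rows.append(node)
        cols.append(feature[par])
        data.append(frac[node] - frac[par])
    op = sparse.csr_matrix(
        (data, (rows, cols)), shape=(n_nodes, n_features)
    )
    return float(frac[0]), op


def contribution_matrix(model: TrainedModel, X: np.ndarray,
                        training_ids: Sequence[int] | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batch decomposition.

    Returns ``(bias, contributions, n_trees_used, oob_flags)`` with shapes
    (n,), (n, p), (n,), (n,).  If ``training_ids`` is given (one id per row,
    or None entries for non-training variants), row i uses only trees whose
    bootstrap excluded ``training_ids[i]``; rows in every tree's bootstrap
    fall back to all trees with ``oob_flags[i] = False`` and a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if p != len(model.feature_names):
        raise ValueError("feature count does not match model schema")

    if training_ids is None:
        eligible = np.ones((model.n_trees, n), dtype=bool)
    else:
        ids = np.array(
            [-1 if t is None else int(t) for t in training_ids], dtype=np.int64
        )
        eligible = np.empty((model.n_trees, n), dtype=bool)
        for t, sample in enumerate(model.per_tree_sample_ids):
            in_bag = np.isin(ids, sample)
            eligible[t] = ~in_bag | (ids < 0)

    n_used = eligible.sum(axis=0)
    oob_flags = np.ones(n, dtype=bool) if training_ids is not None else \
        np.zeros(n, dtype=bool)
    fallback = n_used == 0
    if fallback.any():
        logger.warning(
            "%d variant(s) present in every tree's bootstrap; "
            "falling back to all trees", int(fallback.sum()),
        )
        eligible[:, fallback] = True
        n_used = eligible.sum(axis=0)
        oob_flags[fallback] = False

    bias_acc = np.zeros(n)
    contrib_acc = np.zeros((n, p))
    for t, est in enumerate(model.estimators):
        mask = eligible[t]
        if not mask.any():
            continue
        root_bias, op = _tree_contribution_operator(est, p)
        indicator = est.decision_path(X[mask])
        contrib_acc[mask] += np.asarray((indicator @ op).todense())
        bias_acc[mask] += root_bias
    bias = bias_acc / n_used
    contributions = contrib_acc / n_used[:, None]
    return bias, contributions, n_used, oob_flags


def contributions(model: TrainedModel, x: np.ndarray,
                  training_id: int | None = None) -> ContributionVector:
    """Decompose one variant's score; OOB if ``training_id`` is given."""
    ids = None if training_id is None else [training_id]
    bias, contrib, n_used, oob = contribution_matrix(
        model, np.atleast_2d(x), ids
    )
    return ContributionVector(
        bias=float(bias[0]),
        contributions=contrib[0],
        n_trees_used=int(n_used[0]),
        oob=bool(oob[0]),
    )


@dataclass
class FunctionalProfile:
    """Per-variant display pairing rescaled raw feature values in [-1, 1]
    with their signed contributions."""

    rescaled_values: np.ndarray
    contributions: ContributionVector
    feature_names: list[str] = field(default_factory=list)


class ReferenceDistribution:
    """Empirical per-feature distributions over a background set.

    Raw values are mapped to [-1, 1] by their quantile position: the
    reference minimum maps to -1, the median to 0 and the maximum to +1,
    interpolating linearly in rank space between observed values.  The
    quantile map is robust to the heavy tails of conservation scores.
    """

    def __init__(self, values: Mapping[str, np.ndarray]) -> None:
        self._sorted = {
            name: np.sort(np.asarray(v, dtype=float))
            for name, v in values.items()
            if len(v) > 0
        }

    @classmethod
    def from_matrix(cls, X: np.ndarray, feature_names: Sequence[str]
                    ) -> "ReferenceDistribution":
        return cls({name: X[:, j] for j, name in enumerate(feature_names)})

    def rescale(self, name: str, value: float) -> float:
        ref = self._sorted.get(name)
        if ref is None:
            logger.warning("feature %r absent from reference; rescaled to 0",
                           name)
            return 0.0
        if len(ref) == 1 or ref[0] == ref[-1]:
            return 0.0
        q = float(np.interp(value, ref, np.linspace(0.0, 1.0, len(ref))))
        return 2.0 * q - 1.0


def functional_profile(x: np.ndarray, cv: ContributionVector,
                       reference: ReferenceDistribution,
                       feature_names: Sequence[str]) -> FunctionalProfile:
    rescaled = np.array(
        [reference.rescale(name, float(v))
         for name, v in zip(feature_names, x)]
    )
    return FunctionalProfile(rescaled, cv, list(feature_names))


def plot_profile(profile: FunctionalProfile, path: str | Path,
                 title: str = "") -> None:
    """Bar chart: heights = rescaled feature values, colors = contribution
    sign and magnitude (red positive, blue negative)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    contrib = profile.contributions.contributions
    vmax = max(np.abs(contrib).max(), 1e-12)
    colors = plt.cm.coolwarm(0.5 + contrib / (2 * vmax))
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(range(len(profile.rescaled_values)), profile.rescaled_values,
           color=colors)
    ax.set_xticks(range(len(profile.feature_names)))
    ax.set_xticklabels(profile.feature_names, rotation=90, fontsize=6)
    ax.set_ylim(-1.05, 1.05)
    ax.set_ylabel("rescaled feature value")
    ax.axhline(0, color="black", lw=0.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_contributions_tsv(keys: Sequence, vectors: Sequence[ContributionVector],
                            feature_names: Sequence[str],
                            path: str | Path) -> None:
    import pandas as pd

    rows = []
    for key, cv in zip(keys, vectors):
        row = {"variant": str(key), "bias": cv.bias}
        row.update(dict(zip(feature_names, cv.contributions)))
        row["n_trees_used"] = cv.n_trees_used
        row["oob"] = cv.oob
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
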