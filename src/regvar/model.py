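"""Balanced random-forest classifier for non-coding variant scoring.

Class imbalance is handled inside the ensemble: each of the (default 1,000)
trees is grown on its own balanced bootstrap — n draws with replacement from
each class, n being the size of the smallest class.  The per-tree training
index multisets are retained so that out-of-bag logic (scores and feature
contributions for training variants) can exclude trees that saw a variant.

The score of a variant is the mean, over trees, of the class-1 fraction of
the leaf the variant reaches — with near-pure leaves (min_samples_leaf = 1)
this is the proportion of trees voting "regulatory", and it makes the
additive decomposition in :mod:`regvar.explain` exact.

Indels are scored per position: every reference position affected by the
variant plus one flanking position on each side is evaluated for both
substitution classes (transition and transversion), and the maximum score is
reported together with the full per-position trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .core_io import Variant, VariantType
from .sampling import balanced_per_tree_samples

logger = logging.getLogger(__name__)

_ARCHIVE_FORMAT = 1


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 1000
    max_depth: int = 15
    min_samples_leaf: int = 1
    max_features: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.max_depth <= 0 or self.min_samples_leaf <= 0:
            raise ValueError("forest parameters must be positive")


@dataclass
class TrainedModel:
    estimators: list[DecisionTreeClassifier]
    per_tree_sample_ids: list[np.ndarray]
    feature_names: list[str]
    params: ForestParams
    decision_threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.estimators)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"format": _ARCHIVE_FORMAT, "model": self}, path, compress=3
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format") != _ARCHIVE_FORMAT:
            raise ValueError(f"unsupported model archive {path}")
        return payload["model"]


def train(X: np.ndarray, y: np.ndarray, params: ForestParams,
          feature_names: Sequence[str] | None = None) -> TrainedModel:
    """Fit the balanced forest; per-tree sample multisets are recorded."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]

    samples = balanced_per_tree_samples(y, params.n_trees, params.seed)
    tree_seeds = np.random.SeedSequence(params.seed).generate_state(
        params.n_trees
    ) % (2**31 - 1)

    estimators = []
    for sample, tree_seed in zip(samples, tree_seeds):
        est = DecisionTreeClassifier(
            criterion="gini",
            max_depth=params.max_depth,
            min_samples_leaf=params.min_samples_leaf,
            max_features=params.max_features,
            random_state=int(tree_seed),
        )
        est.fit(X[sample], y[sample])
        estimators.append(est)

    if np.ptp(X, axis=0).max() == 0:
        logger.warning("constant feature matrix: model carries no signal")

    return TrainedModel(
        estimators=estimators,
        per_tree_sample_ids=[np.asarray(s) for s in samples],
        feature_names=list(feature_names),
        params=params,
    )


def _leaf_fraction(est: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Class-1 fraction of the training sample in the leaf each row reaches."""
    proba = est.predict_proba(X)
    col = {c: i for i, c in enumerate(est.classes_)}.get(1)
    if col is None:
        return np.zeros(X.shape[0])
    return proba[:, col]


def score_matrix(model: TrainedModel, X: np.ndarray,
                 tree_mask: np.ndarray | None = None) -> np.ndarray:
    """Mean leaf class-1 fraction over trees (optionally a tree subset)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature count {X.shape[1]} does not match schema "
            f"({len(model.feature_names)})"
        )
    trees = model.estimators
    if tree_mask is not None:
        trees = [t for t, keep in zip(trees, tree_mask) if keep]
        if not trees:
            raise ValueError("empty tree subset")
    acc = np.zeros(X.shape[0])
    for est in trees:
        acc += _leaf_fraction(est, X)
    return acc / len(trees)


def score(model: TrainedModel, x: np.ndarray) -> float:
    """Score a single feature vector; always in [0, 1]."""
    return float(score_matrix(model, np.atleast_2d(x))[0])


@dataclass
class ScoreRecord:
    variant: Variant
    score: float
    evaluated_positions: list[tuple[int, str, float]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if self.evaluated_positions:
            assert abs(
                self.score - max(s for _, _, s in self.evaluated_positions)
            ) < 1e-12


def affected_positions(indel: Variant) -> list[int]:
    """1-based reference positions affected by an indel, plus one flank
    on each side.

    Convention: a deletion affects the deleted bases (the bases present in
    REF beyond the shared prefix with ALT); an insertion affects the anchor
    base.  Both gain one flanking position on each side.
    """
    n_ref, n_alt = len(indel.ref), len(indel.alt)
    if n_ref > n_alt:  # deletion
        core = list(range(indel.pos + n_alt, indel.pos + n_ref))
    elif n_alt > n_ref:  # insertion: the anchor base
        core = [indel.pos]
    else:  # equal-length multi-nucleotide substitution
        core = list(range(indel.pos, indel.pos + n_ref))
    return list(range(core[0] - 1, core[-1] + 2))


def score_indel(model: TrainedModel, indel: Variant,
                annotate_position: Callable[[str, int, VariantType], np.ndarray],
                ) -> ScoreRecord:
    """Max score over (affected ∪ flanking positions) × substitution classes.

    ``annotate_position(contig, pos0, variant_type)`` must return the feature
    vector for a hypothetical substitution of that class at that position.
    """
    if indel.variant_type is not VariantType.INDEL:
        raise ValueError("score_indel expects an indel")
    positions = [p for p in affected_positions(indel) if p >= 1]
    if not positions:
        raise ValueError(f"no on-contig position to evaluate for {indel.key}")
    evaluated: list[tuple[int, str, float]] = []
    for pos in positions:
        for vclass in (VariantType.TRANSITION, VariantType.TRANSVERSION):
            x = annotate_position(indel.contig, pos - 1, vclass)
            evaluated.append((pos, vclass.value, score(model, x)))
    best = max(s for _, _, s in evaluated)
    return ScoreRecord(indel, best, evaluated)


def score_variant(model: TrainedModel, variant: Variant,
                  annotator) -> ScoreRecord:
    """Score an SNV at its own position or an indel over its affected span."""
    if variant.variant_type is VariantType.INDEL:
        return score_indel(model, variant, annotator.annotate_position)
    x = annotator.annotate(variant)
    s = score(model, x)
    return ScoreRecord(variant, s, [(variant.pos, variant.variant_type.value, s)])


def feature_importance(model: TrainedModel) -> np.ndarray:
    """Mean decrease in Gini impurity per feature, normalized to sum to 1."""
    total = np.zeros(len(model.feature_names))
    for est in model.estimators:
        total += est.tree_.compute_feature_importances(normalize=False)
    total /= model.n_trees
    s = total.sum()
    if s == 0:
        logger.warning("all features have zero importance")
        return total
    return total / s
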