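"""Leakage-free cross-validation and discrimination metrics.

Nearby variants share genomic context, so a random train/test split leaks
local information and inflates apparent performance.  Folds are therefore
assigned at the cytogenetic-band level: every variant of a band lands in the
same fold.  ROC AUC uses the trapezoidal rule; PRC AUC uses step-wise
interpolation (average precision) to avoid the optimistic bias of linear
interpolation in precision-recall space.  The decision threshold is the
observed score value maximizing the F1 score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .core_io import CytoBand, IntervalTrack, Variant
from .model import ForestParams, TrainedModel, score_matrix, train
from .sampling import _band_lookup, band_of

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    k: int
    fold_of_variant: np.ndarray  # fold index per variant
    fold_of_band: dict[str, int]
    seed: int


def band_aware_kfold(variants: Sequence[Variant], bands: Sequence[CytoBand],
                     k: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign bands to folds (seeded shuffle + greedy size balancing); each
    variant inherits its band's fold, so same-band variants never straddle
    train and test."""
    if k > len(bands):
        raise ValueError(f"k={k} exceeds the number of bands ({len(bands)})")
    band_index = _band_lookup(bands)
    variant_bands = []
    for v in variants:
        b = band_of(v, band_index)
        if b is None:
            raise ValueError(f"variant {v.key} maps to no cytogenetic band")
        variant_bands.append(b)

    counts: dict[str, int] = {}
    for b in variant_bands:
        counts[b] = counts.get(b, 0) + 1
    # occupied bands first (largest first for balance), then empty bands
    rng = np.random.default_rng(seed)
    band_names = [b.band_name for b in bands]
    rng.shuffle(band_names)
    band_names.sort(key=lambda b: -counts.get(b, 0))

    fold_sizes = np.zeros(k, dtype=int)
    fold_of_band: dict[str, int] = {}
    for name in band_names:
        f = int(np.argmin(fold_sizes))
        fold_of_band[name] = f
        fold_sizes[f] += counts.get(name, 0)

    fold_of_variant = np.array([fold_of_band[b] for b in variant_bands])
    return FoldAssignment(k, fold_of_variant, fold_of_band, seed)


def stratified_kfold(y: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Plain class-stratified folds (the leakage-prone baseline)."""
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros_like(y), y)):
        folds[test_idx] = f
    return folds


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores)))


def prc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-interpolated area under the precision-recall curve."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores)))


def optimal_threshold_f1(scores: Sequence[float], labels: Sequence[int]
                         ) -> tuple[float, float]:
    """Among observed score values (predict positive at score >= t), the
    smallest threshold maximizing F1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    best_t, best_f1 = None, -1.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        if tp == 0:
            continue
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        f1 = 2 * precision * recall / (precision + recall)
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = float(t), float(f1)
    return best_t, best_f1


def confusion_at_threshold(scores: Sequence[float], labels: Sequence[int],
                           threshold: float) -> np.ndarray:
    """2x2 matrix [[TN, FP], [FN, TP]] at predict-positive-if-score>=t."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pred = scores >= threshold
    return np.array([
        [int((~pred & (labels == 0)).sum()), int((pred & (labels == 0)).sum())],
        [int((~pred & (labels == 1)).sum()), int((pred & (labels == 1)).sum())],
    ])


@dataclass
class EvalReport:
    roc_auc: float
    prc_auc: float
    optimal_threshold: float
    f1: float
    confusion: np.ndarray
    roc_points: tuple[np.ndarray, np.ndarray] | None = None
    prc_points: tuple[np.ndarray, np.ndarray] | None = None
    per_fold_roc_auc: list[float] = field(default_factory=list)
    per_fold_prc_auc: list[float] = field(default_factory=list)

    @property
    def mean_fold_roc_auc(self) -> float:
        if self.per_fold_roc_auc:
            return float(np.mean(self.per_fold_roc_auc))
        return self.roc_auc

    @property
    def mean_fold_prc_auc(self) -> float:
        if self.per_fold_prc_auc:
            return float(np.mean(self.per_fold_prc_auc))
        return self.prc_auc

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "prc_auc": self.prc_auc,
            "mean_fold_roc_auc": self.mean_fold_roc_auc,
            "mean_fold_prc_auc": self.mean_fold_prc_auc,
            "optimal_threshold": self.optimal_threshold,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
        }


def evaluate_scores(scores: Sequence[float], labels: Sequence[int],
                    threshold: float | None = None) -> EvalReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    t_opt, f1 = optimal_threshold_f1(scores, labels)
    threshold = t_opt if threshold is None else threshold
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return EvalReport(
        roc_auc=roc_auc(scores, labels),
        prc_auc=prc_auc(scores, labels),
        optimal_threshold=float(t_opt),
        f1=float(f1),
        confusion=confusion_at_threshold(scores, labels, threshold),
        roc_points=(fpr, tpr),
        prc_points=(recall, precision),
    )


def mean_curve(curves: Sequence[tuple[np.ndarray, np.ndarray]],
               n_grid: int = 101
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical averaging on a fixed x grid; band = mean +/- 1.96 sd."""
    grid = np.linspace(0.0, 1.0, n_grid)
    ys = []
    for x, y in curves:
        order = np.argsort(x, kind="stable")
        ys.append(np.interp(grid, x[order], y[order]))
    ys = np.array(ys)
    mean = ys.mean(axis=0)
    half = 1.96 * ys.std(axis=0, ddof=1) if len(ys) > 1 else np.zeros(n_grid)
    return grid, mean, half


def subsample_to_positive_fraction(negatives: Sequence, n_pos: int,
                                   target_fraction: float = 0.125,
                                   seed: int = 0) -> list:
    """Keep m = round(n_pos * (1-f) / f) negatives so positives make up the
    target fraction of the combined set."""
    m = int(round(n_pos * (1.0 - target_fraction) / target_fraction))
    negatives = list(negatives)
    if m >= len(negatives):
        if m > len(negatives):
            logger.warning(
                "negative pool (%d) smaller than required %d; keeping all",
                len(negatives), m,
            )
        return negatives
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=m, replace=False)
    return [negatives[i] for i in sorted(idx)]


@dataclass
class CVResult:
    assignment: FoldAssignment
    fold_models: list[TrainedModel]
    oof_scores: np.ndarray
    labels: np.ndarray
    report: EvalReport


def cross_validate(X: np.ndarray, y: np.ndarray,
                   assignment: FoldAssignment | np.ndarray,
                   params: ForestParams,
                   feature_names: Sequence[str] | None = None) -> CVResult:
    """k-fold CV with per-fold forests; pooled out-of-fold scores plus
    per-fold AUCs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = (assignment.fold_of_variant
             if isinstance(assignment, FoldAssignment) else assignment)
    k = int(folds.max()) + 1
    oof = np.full(len(y), np.nan)
    fold_models: list[TrainedModel] = []
    per_roc, per_prc = [], []
    for f in range(k):
        test = folds == f
        fold_params = ForestParams(
            n_trees=params.n_trees, max_depth=params.max_depth,
            min_samples_leaf=params.min_samples_leaf,
            max_features=params.max_features, seed=params.seed + f,
        )
        m = train(X[~test], y[~test], fold_params, feature_names)
        fold_models.append(m)
        oof[test] = score_matrix(m, X[test])
        if len(np.unique(y[test])) == 2:
            per_roc.append(roc_auc(oof[test], y[test]))
            per_prc.append(prc_auc(oof[test], y[test]))
    report = evaluate_scores(oof, y)
    report.per_fold_roc_auc = per_roc
    report.per_fold_prc_auc = per_prc
    if not isinstance(assignment, FoldAssignment):
        assignment = FoldAssignment(k, folds, {}, params.seed)
    return CVResult(assignment, fold_models, oof, y, report)


@dataclass
class SchemeDataset:
    """One sampling scheme's labeled variants and features."""

    variants: list[Variant]
    X: np.ndarray
    y: np.ndarray


def cross_scheme_evaluate(cv_results: Mapping[str, CVResult],
                          datasets: Mapping[str, SchemeDataset],
                          bands: Sequence[CytoBand],
                          target_fraction: float = 0.125,
                          seed: int = 0) -> dict[tuple[str, str], EvalReport]:
    """Apply each scheme's fold models to every scheme's dataset.

    For model scheme A on dataset scheme B, each of A's k partial models
    scores only the B variants whose band lies in that model's held-out
    fold, so no test variant was seen in training.  Negatives are
    subsampled per fold so positives form ``target_fraction`` of the test
    subset, making curves comparable across schemes.
    """
    band_index = _band_lookup(bands)
    grid: dict[tuple[str, str], EvalReport] = {}
    for model_scheme, cv in cv_results.items():
        fold_of_band = cv.assignment.fold_of_band
        for data_scheme, data in datasets.items():
            if len(data.variants) == 0 or data.y.sum() == len(data.y) \
                    or data.y.sum() == 0:
                raise ValueError(
                    f"dataset {data_scheme!r} must contain both classes"
                )
            scores_all: list[float] = []
            labels_all: list[int] = []
            per_roc, per_prc = [], []
            for f, m in enumerate(cv.fold_models):
                test_idx = [
                    i for i, v in enumerate(data.variants)
                    if fold_of_band.get(band_of(v, band_index)) == f
                ]
                if not test_idx:
                    continue
                pos = [i for i in test_idx if data.y[i] == 1]
                neg = [i for i in test_idx if data.y[i] == 0]
                if not pos or not neg:
                    continue
                neg = subsample_to_positive_fraction(
                    neg, len(pos), target_fraction, seed=seed + f
                )
                idx = pos + neg
                s = score_matrix(m, data.X[idx])
                lab = data.y[idx]
                scores_all.extend(s)
                labels_all.extend(lab)
                per_roc.append(roc_auc(s, lab))
                per_prc.append(prc_auc(s, lab))
            report = evaluate_scores(
                np.array(scores_all), np.array(labels_all)
            )
            report.per_fold_roc_auc = per_roc
            report.per_fold_prc_auc = per_prc
            grid[(model_scheme, data_scheme)] = report
    return grid


def merge_external_scores(frames, on=("contig", "pos", "ref", "alt")):
    """Inner-join externally supplied per-method score tables, dropping
    variants missing a score for any method."""
    import functools

    import pandas as pd

    merged = functools.reduce(
        lambda a, b: pd.merge(a, b, on=list(on), how="inner"), frames
    )
    return merged.dropna()
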