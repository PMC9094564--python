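"""Clustering of contribution profiles and cluster characterization.

Positive variants are grouped by k-means on their per-feature contribution
vectors; K is chosen over a range (default 2-19) by silhouette maximization,
with the inertia curve reported alongside for elbow inspection.  Clusters
are characterized against the rest of the data (other clusters plus
negatives) by standardized effect sizes: Cohen's h (arcsine-square-root
difference of proportions) for binary features and Cohen's d (pooled-SD
standardized mean difference) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .annotation import FeatureSchema


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignment: np.ndarray
    inertia: float
    silhouette: float
    seed: int
    k_diagnostics: dict[int, tuple[float, float]] = field(default_factory=dict)
    # k -> (silhouette, inertia), for the elbow plot


def select_k_and_cluster(contributions: np.ndarray,
                         k_range: tuple[int, int] = (2, 19),
                         seed: int = 0, n_restarts: int = 10) -> ClusterModel:
    """k-means over a K range; returns the silhouette-maximizing model."""
    contributions = np.asarray(contributions, dtype=float)
    k_min, k_max = k_range
    if k_min < 2:
        raise ValueError("k must be at least 2")
    if contributions.shape[0] < k_max + 1:
        raise ValueError(
            f"need at least {k_max + 1} rows for k_max={k_max}"
        )
    if np.ptp(contributions, axis=0).max() == 0:
        raise ValueError("all contribution rows are identical")

    best: ClusterModel | None = None
    diagnostics: dict[int, tuple[float, float]] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(contributions)
        sil = float(silhouette_score(contributions, labels)) \
            if len(np.unique(labels)) > 1 else -1.0
        diagnostics[k] = (sil, float(km.inertia_))
        if best is None or sil > best.silhouette:
            best = ClusterModel(
                k=k, centroids=km.cluster_centers_, assignment=labels,
                inertia=float(km.inertia_), silhouette=sil, seed=seed,
            )
    assert best is not None
    best.k_diagnostics = diagnostics
    return best


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        return math.copysign(math.inf, diff)
    return float(diff / math.sqrt(pooled_var))


def cohens_h(p_a: float, p_b: float) -> float:
    """2 * (arcsin sqrt(p_a) - arcsin sqrt(p_b))."""
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    return 2.0 * (math.asin(math.sqrt(p_a)) - math.asin(math.sqrt(p_b)))


@dataclass
class EffectSize:
    feature: str
    kind: str  # "cohen_d" | "cohen_h"
    value: float


def cluster_vs_rest_effects(cluster_X: np.ndarray, rest_X: np.ndarray,
                            schema: FeatureSchema) -> list[EffectSize]:
    """Per-feature effect size of a cluster against everything else.

    Binary features use Cohen's h on the proportion of nonzero raw values;
    discrete and continuous features use Cohen's d on the raw values.
    """
    cluster_X = np.atleast_2d(cluster_X)
    rest_X = np.atleast_2d(rest_X)
    if cluster_X.shape[0] == 0 or rest_X.shape[0] == 0:
        raise ValueError("both sides must be non-empty")
    out: list[EffectSize] = []
    for j, spec in enumerate(schema):
        if spec.dtype == "binary":
            pa = float(np.mean(cluster_X[:, j] != 0))
            pb = float(np.mean(rest_X[:, j] != 0))
            out.append(EffectSize(spec.name, "cohen_h", cohens_h(pa, pb)))
        else:
            out.append(EffectSize(
                spec.name, "cohen_d",
                cohens_d(cluster_X[:, j], rest_X[:, j]),
            ))
    return out


def cluster_mean_profiles(contributions: np.ndarray,
                          assignment: np.ndarray) -> np.ndarray:
    """Average contribution profile per cluster (rows ordered by cluster id)."""
    ks = np.unique(assignment)
    return np.array([
        contributions[assignment == k].mean(axis=0) for k in ks
    ])


def cluster_composition(assignment: np.ndarray, scores: np.ndarray,
                        labels: np.ndarray, threshold: float) -> list[dict]:
    """True/false-positive composition of each cluster at the model
    threshold (positives only: predicted class vs the threshold)."""
    rows = []
    for k in np.unique(assignment):
        mask = assignment == k
        pred_pos = scores[mask] >= threshold
        rows.append({
            "cluster": int(k),
            "n": int(mask.sum()),
            "n_true_positive": int((pred_pos & (labels[mask] == 1)).sum()),
            "n_false_negative": int((~pred_pos & (labels[mask] == 1)).sum()),
        })
    return rows
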