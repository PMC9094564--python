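"""End-to-end experiment drivers over synthetic data.

These functions wire the pipeline together — simulate, sample controls,
train, cross-validate, explain, rank — at configurable problem sizes, and
return the summary numbers (AUCs, importance ranks, spike-in ranks,
decomposition errors).  They back the command-line ``benchmark`` command and
the reproducibility script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import build_gene_index
from .core_io import Variant
from .evaluation import (
    band_aware_kfold,
    cross_validate,
    roc_auc,
    stratified_kfold,
)
from .explain import contribution_matrix
from .model import ForestParams, ScoreRecord, TrainedModel, score_matrix, train
from .ranking import (
    build_region_index,
    median_rank,
    regions_of_variant,
    spike_in_benchmark,
)
from .sampling import sample_adjusted
from .synthetic_data import (
    Layout,
    SimulatedVariants,
    SimulationConfig,
    simulate_layout,
    simulate_variants,
)


# -- canonical experiment conditions -------------------------------------
# Parameter-recovery runs use the generator defaults (2 x 10 Mb contigs,
# 800 positives, 50k benign pool, 5 informative features at d = 3) with a
# 300-tree forest: ensemble averaging has converged well before that size
# and a 10-fold run stays in the tens of seconds on one CPU.
RECOVERY_FOREST = ForestParams(n_trees=300)

# The leakage comparison needs an unsaturated regime (moderate effect size,
# strong window-shared noise, larger positive clusters) so that the gap
# between random-split and band-aware cross-validation is visible.
LEAKAGE_CFG = SimulationConfig(
    contig_length_bp=2_000_000, n_bands_per_contig=10, n_genes=60,
    n_regulatory_regions=200, n_positives=150, n_negative_pool=4_000,
    effect_size=0.8, autocorr_sd=2.0, positive_cluster_size=8,
)
LEAKAGE_FOREST = ForestParams(n_trees=60)

# Spike-in benchmark scale: 2 x 2 Mb genome, 200 regulatory regions.
SPIKE_CFG = SimulationConfig(
    contig_length_bp=2_000_000, n_bands_per_contig=10, n_genes=60,
    n_regulatory_regions=200, n_positives=200, n_negative_pool=8_000,
)
SPIKE_FOREST = ForestParams(n_trees=100)


def _training_set(cfg: SimulationConfig, layout: Layout,
                  sim: SimulatedVariants, seed: int,
                  positive_fraction: float = 0.125):
    """Adjusted-scheme training set at the given positive fraction."""
    gene_index = build_gene_index(layout.genes)
    positives = sim.positives
    n_neg = int(round(len(positives) * (1 - positive_fraction)
                      / positive_fraction))
    negatives, report = sample_adjusted(
        sim.pool, positives, layout.bands, gene_index, n_neg, seed=seed
    )
    key_to_row = {v.key: i for i, v in enumerate(sim.variants)}
    rows = [key_to_row[v.key] for v in positives + negatives]
    X = sim.X[rows]
    y = np.array([1] * len(positives) + [0] * len(negatives))
    variants = positives + negatives
    return variants, X, y, report


@dataclass
class CVExperimentResult:
    mean_fold_roc_auc: float
    pooled_roc_auc: float
    pooled_prc_auc: float
    optimal_threshold: float
    importance: np.ndarray
    top_features: list[str]
    informative_features: list[str]
    n_variants: int


def band_cv_experiment(cfg: SimulationConfig,
                       forest: ForestParams,
                       k: int = 10, seed: int = 0) -> CVExperimentResult:
    """Adjusted sampling + band-aware k-fold CV + full-data importance."""
    layout = simulate_layout(cfg)
    sim = simulate_variants(cfg, layout)
    variants, X, y, _ = _training_set(cfg, layout, sim, seed)
    assignment = band_aware_kfold(variants, layout.bands, k=k, seed=seed)
    cv = cross_validate(X, y, assignment, forest, sim.schema.names)

    full = train(X, y, forest, sim.schema.names)
    from .model import feature_importance

    imp = feature_importance(full)
    order = np.argsort(-imp)
    truth = sim.truth["informative_features"]
    return CVExperimentResult(
        mean_fold_roc_auc=cv.report.mean_fold_roc_auc,
        pooled_roc_auc=cv.report.roc_auc,
        pooled_prc_auc=cv.report.prc_auc,
        optimal_threshold=cv.report.optimal_threshold,
        importance=imp,
        top_features=[sim.schema.names[j] for j in order[: len(truth)]],
        informative_features=truth,
        n_variants=len(y),
    )


def leakage_experiment(cfg: SimulationConfig, forest: ForestParams,
                       k: int = 5, n_repeats: int = 10, seed: int = 0
                       ) -> list[tuple[float, float]]:
    """(random-split AUC, band-aware AUC) pairs across seeded repeats.

    Random splits may place same-window variants on both sides of the
    train/test divide, so their shared latent noise leaks; band-aware folds
    cannot, and score lower on spatially autocorrelated data.
    """
    out: list[tuple[float, float]] = []
    for r in range(n_repeats):
        rcfg = cfg.with_(seed=cfg.seed + 1000 * r)
        layout = simulate_layout(rcfg)
        sim = simulate_variants(rcfg, layout)
        variants, X, y, _ = _training_set(rcfg, layout, sim, seed + r)

        band_assign = band_aware_kfold(variants, layout.bands, k=k,
                                       seed=seed + r)
        band_cv = cross_validate(X, y, band_assign, forest)

        random_folds = stratified_kfold(y, k=k, seed=seed + r)
        random_cv = cross_validate(X, y, random_folds, forest)
        out.append((random_cv.report.mean_fold_roc_auc,
                    band_cv.report.mean_fold_roc_auc))
    return out


@dataclass
class SpikeInExperimentResult:
    effect_size: float
    median_rank: float
    n_rankable: int
    n_unrankable: int
    mean_candidate_set: float


def spike_in_experiment(cfg: SimulationConfig, forest: ForestParams,
                        effect_sizes: tuple[float, ...] = (0.0, 1.0, 3.0),
                        seed: int = 0,
                        ) -> list[SpikeInExperimentResult]:
    """Spike pathogenic-like variants into a benign background and rank.

    For each effect size the same genome layout and variant positions are
    reused (only the class-conditional feature shift changes).  Half the
    positives train the model; held-out positives inside a regulatory
    region become spike-ins, each assigned a disease gene from a containing
    region's target list.  Background variants are held-out negatives
    inside any region.  Ranks come from disease-gene filtering + score
    ordering; the median spike-in rank should fall as separation grows.
    """
    results: list[SpikeInExperimentResult] = []
    for effect in effect_sizes:
        ecfg = cfg.with_(effect_size=effect)
        layout = simulate_layout(ecfg)
        sim = simulate_variants(ecfg, layout)
        region_index = build_region_index(layout.regions)

        pos_idx = np.flatnonzero(sim.y == 1)
        neg_idx = np.flatnonzero(sim.y == 0)
        rng = np.random.default_rng(seed)
        rng.shuffle(pos_idx)
        rng.shuffle(neg_idx)
        half = len(pos_idx) // 2
        train_pos, held_pos = pos_idx[:half], pos_idx[half:]
        n_train_neg = min(7 * len(train_pos), len(neg_idx) // 2)
        train_neg, held_neg = (neg_idx[:n_train_neg],
                               neg_idx[n_train_neg:])

        rows = np.concatenate([train_pos, train_neg])
        model = train(sim.X[rows],
                      sim.y[rows], forest, sim.schema.names)

        def in_regions(i: int) -> list:
            return regions_of_variant(
                sim.variants[i], layout.regions, region_index
            )

        background: list[ScoreRecord] = []
        bg_rows = [i for i in held_neg if in_regions(i)]
        bg_scores = score_matrix(model, sim.X[bg_rows]) if bg_rows else []
        for i, s in zip(bg_rows, bg_scores):
            background.append(ScoreRecord(sim.variants[i], float(s)))

        pathogenic = []
        spike_rows = [i for i in held_pos if in_regions(i)]
        spike_scores = (score_matrix(model, sim.X[spike_rows])
                        if spike_rows else [])
        for i, s in zip(spike_rows, spike_scores):
            region = in_regions(i)[0]
            gene = sorted(region.target_genes)[0]
            pathogenic.append((
                f"disease_{sim.variants[i].key}",
                ScoreRecord(sim.variants[i], float(s)),
                {gene},
            ))

        bench = spike_in_benchmark(background, pathogenic, layout.regions)
        rankable = [b for b in bench if b.rank is not None]
        results.append(SpikeInExperimentResult(
            effect_size=effect,
            median_rank=median_rank(bench),
            n_rankable=len(rankable),
            n_unrankable=len(bench) - len(rankable),
            mean_candidate_set=float(np.mean(
                [b.candidate_set_size for b in bench]
            )) if bench else float("nan"),
        ))
    return results


def contribution_identity_error(model: TrainedModel, X: np.ndarray,
                                training_ids=None) -> float:
    """Max |score - (bias + sum of contributions)| over rows, with scores
    computed over the same tree subsets used for the decomposition."""
    bias, contrib, n_used, _ = contribution_matrix(model, X, training_ids)
    decomposed = bias + contrib.sum(axis=1)

    if training_ids is None:
        direct = score_matrix(model, X)
        return float(np.max(np.abs(decomposed - direct)))
    ids = np.array([-1 if t is None else int(t) for t in training_ids])
    worst = 0.0
    for i in range(X.shape[0]):
        if ids[i] < 0:
            mask = None
        else:
            mask = np.array([
                ids[i] not in sample
                for sample in model.per_tree_sample_ids
            ])
            if not mask.any():
                mask = None
        direct = score_matrix(model, X[i: i + 1], tree_mask=mask)[0]
        worst = max(worst, abs(decomposed[i] - direct))
    return float(worst)
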