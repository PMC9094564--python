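import numpy as np
import pytest

from regvar.core_io import CytoBand, GenomicInterval, Variant
from regvar.evaluation import (
    SchemeDataset,
    band_aware_kfold,
    confusion_at_threshold,
    cross_scheme_evaluate,
    cross_validate,
    evaluate_scores,
    mean_curve,
    optimal_threshold_f1,
    prc_auc,
    roc_auc,
    stratified_kfold,
    subsample_to_positive_fraction,
)
from regvar.model import ForestParams

from _oracles import f1_sweep_oracle, mann_whitney_auc


def _bands(n, size=1000):
    return [
        CytoBand(GenomicInterval("chr1", i * size, (i + 1) * size), f"1q{i:02d}")
        for i in range(n)
    ]


def _variants_in_bands(bands, per_band):
    out = []
    for band in bands:
        start = band.interval.start
        for j in range(per_band):
            out.append(Variant("chr1", start + 10 * j + 1, "A", "G"))
    return out


class TestBandAwareFolds:
    def test_more_folds_than_bands_is_an_error(self):
        bands = _bands(1)
        with pytest.raises(ValueError, match="exceeds"):
            band_aware_kfold(_variants_in_bands(bands, 3), bands, k=2)

    def test_ten_equal_bands_ten_folds_one_band_each(self):
        bands = _bands(10)
        variants = _variants_in_bands(bands, 5)
        fa = band_aware_kfold(variants, bands, k=10, seed=0)
        assert sorted(fa.fold_of_band.values()) == sorted(range(10))
        counts = np.bincount(fa.fold_of_variant, minlength=10)
        assert np.all(counts == 5)

    def test_same_band_variants_always_share_a_fold(self):
        bands = _bands(7)
        variants = _variants_in_bands(bands, 11)
        for seed in range(5):
            fa = band_aware_kfold(variants, bands, k=3, seed=seed)
            for b in range(7):
                folds = fa.fold_of_variant[b * 11: (b + 1) * 11]
                assert len(set(folds.tolist())) == 1

    def test_close_variants_same_band_same_fold(self):
        bands = _bands(5)
        v1 = Variant("chr1", 100, "A", "G")
        v2 = Variant("chr1", 200, "C", "T")  # 100 bp apart, same band
        fa = band_aware_kfold([v1, v2], bands, k=2, seed=3)
        assert fa.fold_of_variant[0] == fa.fold_of_variant[1]

    def test_variant_outside_all_bands_is_an_error(self):
        bands = _bands(3)
        with pytest.raises(ValueError, match="no cytogenetic band"):
            band_aware_kfold([Variant("chr1", 99999, "A", "G")], bands, k=2)

    def test_folds_partition_the_variants(self):
        bands = _bands(12)
        variants = _variants_in_bands(bands, 4)
        fa = band_aware_kfold(variants, bands, k=4, seed=1)
        assert len(fa.fold_of_variant) == len(variants)
        assert set(fa.fold_of_variant.tolist()) == set(range(4))


class TestDiscriminationMetrics:
    def test_perfect_ordering_gives_auc_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        assert roc_auc(scores, labels) == 1.0
        assert prc_auc(scores, labels) == 1.0

    def test_single_pair(self):
        assert roc_auc([0.9, 0.1], [1, 0]) == 1.0
        assert prc_auc([0.9, 0.1], [1, 0]) == 1.0

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])
        with pytest.raises(ValueError):
            prc_auc([0.5, 0.6], [0, 0])

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_roc_auc_equals_normalized_mann_whitney_u(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(10, 80))
            # discretized scores force ties
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )


class TestThresholdSelection:
    def test_separable_scores_return_smallest_maximizing_threshold(self):
        scores = [0.8, 0.8, 0.2, 0.2]
        labels = [1, 1, 0, 0]
        t, f1 = optimal_threshold_f1(scores, labels)
        assert t == 0.8 and f1 == 1.0

    def test_perfect_binary_scores(self):
        t, f1 = optimal_threshold_f1([1, 1, 0, 0], [1, 1, 0, 0])
        assert f1 == 1.0

    def test_anti_ordered_scores_match_sweep_oracle(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([1, 1, 0, 0])
        assert optimal_threshold_f1(scores, labels) == \
            f1_sweep_oracle(scores, labels)

    def test_random_cases_match_sweep_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(6, 60))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            t, f1 = optimal_threshold_f1(scores, labels)
            t_o, f1_o = f1_sweep_oracle(scores, labels)
            assert f1 == pytest.approx(f1_o, abs=1e-12)
            assert t == pytest.approx(t_o, abs=1e-12)

    def test_confusion_matrix_sums_to_n(self):
        scores = np.array([0.9, 0.6, 0.4, 0.2])
        labels = np.array([1, 0, 1, 0])
        conf = confusion_at_threshold(scores, labels, 0.5)
        assert conf.sum() == 4
        # TN=1 (0.2), FP=1 (0.6), FN=1 (0.4), TP=1 (0.9)
        assert conf.tolist() == [[1, 1], [1, 1]]


class TestPositiveFractionSubsampling:
    def test_paper_scale_fraction(self):
        negatives = list(range(20_000))
        kept = subsample_to_positive_fraction(negatives, 877, 0.125, seed=0)
        frac = 877 / (877 + len(kept))
        assert abs(frac - 0.125) < 1 / (877 + len(kept))

    @pytest.mark.parametrize("n_pos,f,expected_m", [
        (10, 0.5, 10),
        (1, 0.125, 7),
    ])
    def test_round_formula(self, n_pos, f, expected_m):
        kept = subsample_to_positive_fraction(
            list(range(1000)), n_pos, f, seed=0
        )
        assert len(kept) == expected_m

    def test_small_pool_keeps_all(self):
        kept = subsample_to_positive_fraction([1, 2, 3], 100, 0.125, seed=0)
        assert kept == [1, 2, 3]

    def test_deterministic(self):
        a = subsample_to_positive_fraction(list(range(100)), 5, 0.2, seed=3)
        b = subsample_to_positive_fraction(list(range(100)), 5, 0.2, seed=3)
        assert a == b


def test_stratified_folds_partition_and_balance():
    y = np.array([1] * 20 + [0] * 80)
    folds = stratified_kfold(y, k=5, seed=0)
    assert set(folds.tolist()) == set(range(5))
    for f in range(5):
        assert y[folds == f].sum() == 4  # positives evenly spread


def test_mean_curve_constant_curves_have_zero_band():
    x = np.linspace(0, 1, 20)
    curves = [(x, x**2)] * 3
    grid, mean, half = mean_curve(curves)
    assert np.allclose(half, 0.0)
    assert mean[0] == pytest.approx(0.0) and mean[-1] == pytest.approx(1.0)


def test_evaluate_scores_report_fields():
    rng = np.random.default_rng(3)
    scores = np.concatenate([rng.normal(0.7, 0.15, 50),
                             rng.normal(0.3, 0.15, 200)]).clip(0, 1)
    labels = np.array([1] * 50 + [0] * 200)
    report = evaluate_scores(scores, labels)
    assert 0.8 < report.roc_auc <= 1.0
    assert report.confusion.sum() == 250
    assert 0 < report.optimal_threshold < 1


class TestCrossSchemeEvaluation:
    def _setup(self):
        rng = np.random.default_rng(4)
        bands = _bands(8, size=10_000)
        n_pos, n_neg = 60, 240

        def make(shift):
            variants, X, y = [], [], []
            for i in range(n_pos + n_neg):
                band = bands[i % len(bands)]
                variants.append(Variant(
                    "chr1", band.interval.start + 20 * (i // len(bands)) + 1,
                    "A", "G",
                ))
                label = 1 if i < n_pos else 0
                mean = 2.0 if label else shift
                X.append(rng.normal(mean, 1.0, 4))
                y.append(label)
            return SchemeDataset(variants, np.array(X), np.array(y))

        easy = make(shift=-1.0)   # negatives far from positives
        hard = make(shift=1.0)    # negatives close to positives
        datasets = {"easy": easy, "hard": hard}
        params = ForestParams(n_trees=30, seed=0)
        cv_results = {}
        for name, data in datasets.items():
            fa = band_aware_kfold(data.variants, bands, k=4, seed=0)
            cv_results[name] = cross_validate(data.X, data.y, fa, params)
        return cv_results, datasets, bands

    def test_grid_complete_and_bounded(self):
        cv_results, datasets, bands = self._setup()
        grid = cross_scheme_evaluate(cv_results, datasets, bands, seed=0)
        assert set(grid) == {(m, d) for m in datasets for d in datasets}
        for report in grid.values():
            assert 0.0 <= report.roc_auc <= 1.0

    def test_easy_negatives_score_higher_than_hard_for_any_model(self):
        cv_results, datasets, bands = self._setup()
        grid = cross_scheme_evaluate(cv_results, datasets, bands, seed=0)
        for m in ("easy", "hard"):
            assert grid[(m, "easy")].roc_auc >= grid[(m, "hard")].roc_auc

    def test_single_class_dataset_is_an_error(self):
        cv_results, datasets, bands = self._setup()
        broken = SchemeDataset(
            datasets["easy"].variants[:5],
            datasets["easy"].X[:5],
            np.ones(5, dtype=int),
        )
        with pytest.raises(ValueError, match="both classes"):
            cross_scheme_evaluate(
                cv_results, {"easy": broken}, bands, seed=0
            )
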