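"""LOSO protocol, RBF-SVM wrappers and the two-step grid search."""

import numpy as np
import pytest

import hingeforce as hf
from hingeforce.classify import (
    FineSpec,
    GridSpec,
    SvmConfig,
    grid_search,
    loso_cross_val,
    make_loso_splits,
    predict,
    train,
)
from hingeforce.features import FeatureVector, feature_names
from hingeforce.pipeline import featurize_cohort


def gaussian_vectors(rng, means, n_per_class, subjects=("A", "B"), spread=0.1):
    """Synthetic 84-d feature vectors: one Gaussian blob per behavior class."""
    names = tuple(feature_names())
    vectors = []
    for subject in subjects:
        for label, mean in means.items():
            center = np.zeros(84)
            center[:3] = mean
            for _ in range(n_per_class):
                vectors.append(
                    FeatureVector(
                        values=center + rng.normal(0, spread, 84),
                        names=names,
                        label=label,
                        subject_id=subject,
                    )
                )
    return vectors


@pytest.fixture()
def separable_vectors():
    rng = np.random.default_rng(17)
    means = {
        hf.Behavior.NHM: 0.0,
        hf.Behavior.LC: 5.0,
        hf.Behavior.RC: -5.0,
    }
    return gaussian_vectors(rng, means, n_per_class=10)


class TestLosoSplits:
    def test_one_fold_per_subject(self, small_vectors):
        splits = make_loso_splits(small_vectors)
        subjects = sorted({v.subject_id for v in small_vectors})
        assert len(splits.folds) == len(subjects)
        assert sorted(test for _, test in splits.folds) == subjects

    def test_two_subject_folds(self, separable_vectors):
        splits = make_loso_splits(separable_vectors)
        assert len(splits.folds) == 2
        for train_ids, test_id in splits.folds:
            assert len(train_ids) == 1
            assert test_id not in train_ids

    def test_test_sets_partition_all_windows(self, small_vectors):
        splits = make_loso_splits(small_vectors)
        seen = []
        for _, test_id in splits.folds:
            seen += [i for i, v in enumerate(small_vectors) if v.subject_id == test_id]
        assert sorted(seen) == list(range(len(small_vectors)))

    def test_single_subject_rejected(self, separable_vectors):
        only_a = [v for v in separable_vectors if v.subject_id == "A"]
        with pytest.raises(ValueError):
            make_loso_splits(only_a)


class TestTrainPredict:
    def test_separable_classes_reach_perfect_training_accuracy(self, separable_vectors):
        model = train(separable_vectors, SvmConfig(C=16, gamma=0.01))
        pred = predict(model, separable_vectors)
        truth = np.array([v.label.value for v in separable_vectors])
        assert np.mean(pred == truth) == 1.0

    def test_training_accuracy_bounds_heldout_accuracy(self):
        # optimism property, over 10 generator seeds
        config = SvmConfig(C=16, gamma=2.0**-7)
        for seed in range(10):
            vectors = featurize_cohort(hf.generate_cohort(3, 3, seed=seed))
            splits = make_loso_splits(vectors)
            heldout_acc, _ = loso_cross_val(vectors, config, splits)
            from hingeforce.features import apply_scaler, fit_scaler

            scaler = fit_scaler(vectors)
            scaled = apply_scaler(scaler, vectors)
            model = train(scaled, config)
            train_acc = np.mean(
                predict(model, scaled) == [v.label.value for v in vectors]
            )
            assert train_acc >= heldout_acc - 1e-12

    def test_vanishing_gamma_gives_near_constant_predictions(self):
        rng = np.random.default_rng(19)
        # unbalanced classes so the flat-kernel majority vote is well defined
        majority = gaussian_vectors(rng, {hf.Behavior.LC: 1.0}, n_per_class=15)
        minority = gaussian_vectors(rng, {hf.Behavior.RC: -1.0}, n_per_class=5)
        vectors = majority + minority
        model = train(vectors, SvmConfig(C=1.0, gamma=1e-12))
        pred = predict(model, vectors)
        assert len(set(pred)) == 1

    def test_single_class_training_rejected(self, separable_vectors):
        lc_only = [v for v in separable_vectors if v.label is hf.Behavior.LC]
        with pytest.raises(ValueError):
            train(lc_only, SvmConfig(C=1, gamma=0.1))

    def test_permuting_training_order_leaves_predictions_unchanged(
        self, separable_vectors
    ):
        rng = np.random.default_rng(23)
        config = SvmConfig(C=4, gamma=0.05)
        shuffled = list(separable_vectors)
        rng.shuffle(shuffled)
        model_a = train(separable_vectors, config)
        model_b = train(shuffled, config)
        np.testing.assert_array_equal(
            predict(model_a, separable_vectors), predict(model_b, separable_vectors)
        )


class TestGridSearch:
    def test_single_pair_grid(self, separable_vectors):
        spec = GridSpec(log2_C=(2.0,), log2_gamma=(-3.0,))
        result = grid_search(separable_vectors, coarse=spec, fine=None)
        assert result.best == SvmConfig(C=4.0, gamma=0.125)
        assert result.best_accuracy == max(acc for _, acc in result.grid)

    def test_ties_prefer_smallest_c_then_gamma(self, separable_vectors):
        spec = GridSpec(log2_C=(0.0, 4.0), log2_gamma=(-7.0, -5.0))
        result = grid_search(separable_vectors, coarse=spec, fine=None)
        top = max(acc for _, acc in result.grid)
        candidates = [cfg for cfg, acc in result.grid if acc == top]
        assert result.best == min(candidates, key=lambda c: (c.C, c.gamma))

    def test_fine_grid_centers_on_coarse_optimum(self):
        spec = FineSpec(span=1.0, step=0.5)
        around = spec.around(SvmConfig(C=16.0, gamma=1.0))
        assert set(around.log2_C) == {3.0, 3.5, 4.0, 4.5, 5.0}
        assert set(around.log2_gamma) == {-1.0, -0.5, 0.0, 0.5, 1.0}

    def test_surface_records_every_pair(self, separable_vectors):
        spec = GridSpec(log2_C=(0.0, 2.0), log2_gamma=(-5.0, -3.0))
        result = grid_search(separable_vectors, coarse=spec, fine=None)
        assert len(result.grid) == 4
        assert all(0 <= acc <= 1 for _, acc in result.grid)

    def test_empty_grid_rejected(self, separable_vectors):
        with pytest.raises(ValueError):
            grid_search(
                separable_vectors, coarse=GridSpec(log2_C=(), log2_gamma=()), fine=None
            )

    def test_best_accuracy_reproducible(self, separable_vectors):
        spec = GridSpec(log2_C=(0.0,), log2_gamma=(-5.0,))
        a = grid_search(separable_vectors, coarse=spec, fine=None)
        b = grid_search(separable_vectors, coarse=spec, fine=None)
        assert a.best_accuracy == b.best_accuracy
        np.testing.assert_array_equal(a.best_predictions, b.best_predictions)
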