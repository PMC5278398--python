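"""RBF-SVM classification with leave-one-subject-out cross-validation.

The classifier is a multiclass support-vector machine with a radial basis
function kernel k(u, v) = exp(-gamma ||u - v||^2), trained one-vs-one (the
margin solver is scikit-learn's SVC; this module's own content is the
cross-validation protocol, the two-step exponential grid search and the
leakage discipline).

Model selection follows a two-step grid search over exponentially spaced
(C, gamma) pairs: a coarse lattice at two-octave steps, then a fine lattice
at quarter-octave steps centered on the coarse optimum.  Every pair is
scored by leave-one-subject-out (LOSO) cross-validation — each fold holds
out all windows of one subject, so the score measures generalization to an
unseen person — with the feature scaler refit on each fold's training
subjects only.  Accuracy is pooled window-level accuracy over all folds.
Ties in grid accuracy prefer the smaller C, then the smaller gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from hingeforce.behaviors import Behavior
from hingeforce.features import FeatureVector, apply_scaler, fit_scaler


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters: margin penalty C and kernel width gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be strictly positive")


@dataclass(frozen=True)
class GridSpec:
    """An exponential (C, gamma) lattice given by base-2 exponents."""

    log2_C: tuple[float, ...] = tuple(range(-5, 16, 2))
    log2_gamma: tuple[float, ...] = tuple(range(-15, 4, 2))

    def configs(self) -> list[SvmConfig]:
        return [
            SvmConfig(C=2.0**lc, gamma=2.0**lg)
            for lc in self.log2_C
            for lg in self.log2_gamma
        ]


@dataclass(frozen=True)
class FineSpec:
    """Fine lattice: +/- span octaves around the coarse optimum, at step octaves."""

    span: float = 2.0
    step: float = 0.25

    def around(self, best: SvmConfig) -> GridSpec:
        lc = np.log2(best.C)
        lg = np.log2(best.gamma)
        offsets = np.arange(-self.span, self.span + self.step / 2, self.step)
        return GridSpec(
            log2_C=tuple(lc + offsets), log2_gamma=tuple(lg + offsets)
        )


@dataclass(frozen=True)
class CvSplit:
    """Leave-one-subject-out folds: (training subject ids, held-out subject id)."""

    folds: tuple[tuple[tuple[str, ...], str], ...]


@dataclass
class GridSearchResult:
    """Full accuracy surface of a grid search plus the selected model."""

    grid: list[tuple[SvmConfig, float]]
    best: SvmConfig
    best_accuracy: float
    #: pooled out-of-fold predicted labels for the best config, aligned with
    #: the input vector order
    best_predictions: np.ndarray = field(repr=False)


def make_loso_splits(vectors: list[FeatureVector]) -> CvSplit:
    """One fold per subject; every subject is held out exactly once."""
    subjects = sorted({v.subject_id for v in vectors})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 distinct subjects")
    folds = tuple(
        (tuple(s for s in subjects if s != test), test) for test in subjects
    )
    return CvSplit(folds=folds)


def train(vectors: list[FeatureVector], config: SvmConfig) -> SVC:
    """Fit a one-vs-one RBF-SVM on scaled feature vectors."""
    labels = {v.label for v in vectors}
    if len(labels) < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = np.stack([v.values for v in vectors])
    y = np.array([v.label.value for v in vectors])
    model = SVC(C=config.C, gamma=config.gamma, kernel="rbf", cache_size=256)
    model.fit(X, y)
    return model


def predict(model: SVC, vectors: list[FeatureVector]) -> np.ndarray:
    """Predicted integer behavior labels (1-6) for each vector."""
    X = np.stack([v.values for v in vectors])
    if X.shape[1] != model.n_features_in_:
        raise ValueError("feature dimension does not match the trained model")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature values must be finite")
    return model.predict(X)


def loso_cross_val(
    vectors: list[FeatureVector],
    config: SvmConfig,
    splits: CvSplit | None = None,
) -> tuple[float, np.ndarray]:
    """Pooled LOSO accuracy and out-of-fold predictions for one (C, gamma).

    In each fold the scaler is fit on the training subjects only and applied
    to both sides, so the held-out subject never influences scaling or
    training.
    """
    if splits is None:
        splits = make_loso_splits(vectors)
    y_true = np.array([v.label.value for v in vectors])
    y_pred = np.zeros(len(vectors), dtype=int)
    for train_ids, test_id in splits.folds:
        train_idx = [i for i, v in enumerate(vectors) if v.subject_id in train_ids]
        test_idx = [i for i, v in enumerate(vectors) if v.subject_id == test_id]
        train_vecs = [vectors[i] for i in train_idx]
        test_vecs = [vectors[i] for i in test_idx]
        scaler = fit_scaler(train_vecs)
        model = train(apply_scaler(scaler, train_vecs), config)
        y_pred[test_idx] = predict(model, apply_scaler(scaler, test_vecs))
    return float(np.mean(y_pred == y_true)), y_pred


def _search(
    vectors: list[FeatureVector], spec: GridSpec, splits: CvSplit
) -> tuple[list[tuple[SvmConfig, float]], SvmConfig, float, np.ndarray]:
    configs = spec.configs()
    if not configs:
        raise ValueError("empty grid")
    surface = []
    best = None
    best_acc = -1.0
    best_pred = None
    for config in configs:
        acc, pred = loso_cross_val(vectors, config, splits)
        surface.append((config, acc))
        # strict improvement only: earlier (smaller C, then gamma) wins ties
        key = (acc, -config.C, -config.gamma)
        if best is None or key > (best_acc, -best.C, -best.gamma):
            best, best_acc, best_pred = config, acc, pred
    return surface, best, best_acc, best_pred


def grid_search(
    vectors: list[FeatureVector],
    coarse: GridSpec | None = None,
    fine: FineSpec | None = FineSpec(),
    splits: CvSplit | None = None,
) -> GridSearchResult:
    """Two-step exponential grid search scored by LOSO accuracy.

    The coarse lattice is searched first; if ``fine`` is given, a fine
    lattice centered on the coarse optimum is searched next.  The returned
    surface concatenates both passes.
    """
    if coarse is None:
        coarse = GridSpec()
    if splits is None:
        splits = make_loso_splits(vectors)
    surface, best, best_acc, best_pred = _search(vectors, coarse, splits)
    if fine is not None:
        fine_surface, fine_best, fine_acc, fine_pred = _search(
            vectors, fine.around(best), splits
        )
        surface = surface + fine_surface
        if (fine_acc, -fine_best.C, -fine_best.gamma) > (best_acc, -best.C, -best.gamma):
            best, best_acc, best_pred = fine_best, fine_acc, fine_pred
    return GridSearchResult(
        grid=surface, best=best, best_accuracy=best_acc, best_predictions=best_pred
    )
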