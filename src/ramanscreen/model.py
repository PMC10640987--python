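"""PCA feature extraction and one-vs-all SVM classification.

PCA (via SVD) is fit on training spectra only and retains the smallest
number of components whose cumulative explained variance reaches the
target (default 99%). Classification uses three soft-margin RBF SVMs in a
one-vs-all arrangement; hyperparameters (C, gamma) are selected by
stratified inner cross-validation on the training data alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .spectrum import CLASS_LABELS


class ModelError(ValueError):
    """Raised for invalid model inputs or configuration."""


def default_hyper_grid(n_features: int) -> list[tuple[float, float]]:
    """(C, gamma) candidates: C in {0.1,1,10,100}, gamma in {1e-3..1}/n_features."""
    return [
        (C, g / n_features)
        for C in (0.1, 1.0, 10.0, 100.0)
        for g in (0.001, 0.01, 0.1, 1.0)
    ]


def reduced_hyper_grid(n_features: int) -> list[tuple[float, float]]:
    """Coarse grid for permutation controls and quick runs."""
    return [(C, g / n_features) for C in (1.0, 10.0) for g in (0.01, 0.1)]


@dataclass
class PCAModel:
    """Trained PCA: training mean, orthonormal loadings, variance ratios."""

    mean_vector: np.ndarray
    loadings: np.ndarray            # (n_components, n_channels)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])


@dataclass
class SVMModelSet:
    """One binary decision function per class, in fixed class order.

    Scores are standardized (training mean/std) before the kernel, so the
    (C, gamma) grid operates on unit-scale features.
    """

    classes: tuple[str, ...]
    models: dict[str, SVC]
    C: float
    gamma: float
    kernel: str = "rbf"
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None


def pca_fit(train_matrix: np.ndarray, variance_target: float = 0.99) -> PCAModel:
    """Fit PCA on training rows, keeping the smallest k reaching the target.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so the decomposition is deterministic.
    """
    X = np.asarray(train_matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ModelError("pca_fit needs a 2-D matrix with >= 2 rows")
    if not 0 < variance_target <= 1.0:
        raise ModelError("variance_target must be in (0, 1]")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    reached = np.nonzero(cum >= variance_target - 1e-12)[0]
    if reached.size:
        k = int(reached[0]) + 1
    else:  # total variance never reaches the target: keep everything
        k = int(np.count_nonzero(evr > 1e-15)) or 1
    loadings = pca.components_[:k].copy()
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(
        mean_vector=pca.mean_.copy(),
        loadings=loadings,
        explained_variance_ratio=evr[:k].copy(),
    )


def pca_transform(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Project (rows - training mean) onto the loadings."""
    X = np.atleast_2d(np.asarray(matrix, float))
    if X.shape[1] != model.mean_vector.size:
        raise ModelError(
            f"channel count {X.shape[1]} != model {model.mean_vector.size}"
        )
    return (X - model.mean_vector) @ model.loadings.T


def _score_scaler(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # single global scale: brings scores to O(1) for the (C, gamma) grid
    # without reweighting components (per-component standardization would
    # amplify noise directions relative to the leading PCs)
    mean = scores.mean(axis=0)
    std = float((scores - mean).std())
    return mean, np.array(std if std > 0 else 1.0)


def _fit_ova(
    scores: np.ndarray, labels: np.ndarray, C: float, gamma: float, kernel: str
) -> dict[str, SVC]:
    models: dict[str, SVC] = {}
    for cls in CLASS_LABELS:
        y = (labels == cls).astype(int)
        clf = SVC(C=C, gamma=gamma, kernel=kernel)
        clf.fit(scores, y)
        models[cls] = clf
    return models


def _decision_matrix(models: dict[str, SVC], scores: np.ndarray) -> np.ndarray:
    return np.column_stack([models[cls].decision_function(scores) for cls in CLASS_LABELS])


def svm_train_ova(
    scores: np.ndarray,
    labels: np.ndarray,
    hyper_grid: list[tuple[float, float]] | None = None,
    inner_folds: int = 5,
    rng: np.random.Generator | int | None = None,
    kernel: str = "rbf",
) -> SVMModelSet:
    """Select (C, gamma) by stratified inner CV, then refit one-vs-all SVMs.

    Candidates are scored by mean multiclass accuracy over ``inner_folds``
    stratified folds of the training data only; ties go to the smallest C,
    then the smallest gamma. The winner is refit on all training rows as
    three binary one-vs-all classifiers.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ModelError("scores and labels length mismatch")
    present = set(np.unique(labels))
    missing = [c for c in CLASS_LABELS if c not in present]
    if missing:
        raise ModelError(f"class absent from training data: {missing[0]}")
    if scores.shape[0] < inner_folds:
        raise ModelError("fewer samples than inner folds")
    if hyper_grid is None:
        hyper_grid = default_hyper_grid(scores.shape[1])

    if rng is None:
        seed = 0
    elif isinstance(rng, (int, np.integer)):
        seed = int(rng)
    else:  # np.random.Generator
        seed = int(rng.integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(scores, labels))

    # per-fold scalers, fit on the inner-train portion only
    fold_data = []
    for tr, va in splits:
        if len(set(labels[tr])) < len(CLASS_LABELS):
            continue
        mean, std = _score_scaler(scores[tr])
        fold_data.append(
            ((scores[tr] - mean) / std, labels[tr], (scores[va] - mean) / std, labels[va])
        )

    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    for C, gamma in sorted(hyper_grid):
        correct = 0
        total = 0
        for str_, ltr, sva, lva in fold_data:
            models = _fit_ova(str_, ltr, C, gamma, kernel)
            pred = svm_predict_models(models, sva)[0]
            correct += int(np.sum(pred == lva))
            total += lva.size
        acc = correct / total if total else 0.0
        if best is None or acc > best[0] + 1e-12:
            best = (acc, C, gamma)
    assert best is not None
    _, C, gamma = best
    mean, std = _score_scaler(scores)
    models = _fit_ova((scores - mean) / std, labels, C, gamma, kernel)
    return SVMModelSet(
        classes=CLASS_LABELS, models=models, C=C, gamma=gamma, kernel=kernel,
        scale_mean=mean, scale_std=std,
    )


def svm_predict_models(
    models: dict[str, SVC], scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    decisions = _decision_matrix(models, np.atleast_2d(scores))
    idx = np.argmax(decisions, axis=1)  # argmax takes the first max: fixed tie order
    labels = np.array([CLASS_LABELS[i] for i in idx])
    return labels, decisions


def svm_predict(model_set: SVMModelSet, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict by maximal one-vs-all decision value; ties -> first class in order.

    Returns ``(labels, decision_values)`` with decision values in the fixed
    class order (cancer, benign, normal) for downstream ROC construction.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    n_expected = model_set.models[CLASS_LABELS[0]].n_features_in_
    if scores.shape[1] != n_expected:
        raise ModelError(f"score dimension {scores.shape[1]} != training {n_expected}")
    if model_set.scale_mean is not None:
        scores = (scores - model_set.scale_mean) / model_set.scale_std
    return svm_predict_models(model_set.models, scores)


__all__ = [
    "PCAModel",
    "SVMModelSet",
    "ModelError",
    "default_hyper_grid",
    "reduced_hyper_grid",
    "pca_fit",
    "pca_transform",
    "svm_train_ova",
    "svm_predict",
]
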