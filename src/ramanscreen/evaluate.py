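"""Dual-layer cross-validation, metrics, ROC/AUC, and permutation control.

The outer layer estimates generalization: a stratified 5-fold partition in
which each fold serves once as an untouched 20% test set while the other
80% is used for model building (PCA fit and inner 5-fold hyperparameter
selection). The partition is redrawn ``repeats`` times (default 20, i.e.
100 model fits) and every metric is reported as mean +/- std with a
percentile 95% CI over repeats. A literal repeated 80/20 holdout scheme is
available as an alternative outer scheme.

The permutation control reruns the identical pipeline with class labels
randomly permuted; chance-level accuracy there certifies that the
unpermuted result reflects label-correlated spectral structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .model import (
    default_hyper_grid,
    pca_fit,
    pca_transform,
    svm_predict,
    svm_train_ova,
)
from .spectrum import CLASS_LABELS


class EvaluationError(ValueError):
    """Raised for invalid evaluation inputs."""


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation design.

    ``five_fold_outer`` (default): per repeat, a stratified 5-fold outer
    partition in which every sample is tested exactly once.
    ``repeated_holdout_80_20``: per repeat, one stratified 80/20 split.
    """

    outer_scheme: str = "five_fold_outer"
    inner_folds: int = 5
    repeats: int = 20
    stratified: bool = True
    seed: int = 0
    variance_target: float = 0.99
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.outer_scheme not in ("five_fold_outer", "repeated_holdout_80_20"):
            raise EvaluationError(f"unknown outer scheme {self.outer_scheme!r}")
        if self.repeats < 1:
            raise EvaluationError("repeats must be >= 1")
        if self.inner_folds < 2:
            raise EvaluationError("inner_folds must be >= 2")


@dataclass
class CVResult:
    """Per-repeat confusion matrices, per-class metrics, and aggregates."""

    confusions: np.ndarray        # (repeats, 3, 3), rows true, cols predicted
    sensitivity: np.ndarray       # (repeats, 3)
    specificity: np.ndarray       # (repeats, 3)
    accuracy_class: np.ndarray    # (repeats, 3), one-vs-rest accuracy
    auc: np.ndarray               # (repeats, 3), one-vs-rest AUC
    overall_accuracy: np.ndarray  # (repeats,)
    classes: tuple[str, ...] = CLASS_LABELS
    # pooled out-of-fold truth/decisions of the first repeat, kept for
    # plotting representative ROC sweeps
    example_true: np.ndarray | None = None
    example_decisions: np.ndarray | None = None

    def roc_curves(self) -> dict[str, "ROCCurve"]:
        """Representative ROC curves from the first repeat's pooled decisions."""
        if self.example_true is None or self.example_decisions is None:
            raise EvaluationError("no pooled decisions stored")
        return {
            cls: roc_auc_ovr(self.example_decisions[:, j], self.example_true, cls)
            for j, cls in enumerate(self.classes)
        }

    def metrics_table(self) -> pd.DataFrame:
        """Aggregate to a tidy class x metric table (mean, std, 95% CI)."""
        rows = []
        per_metric = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy_class,
            "auc": self.auc,
        }
        for j, cls in enumerate(self.classes):
            for metric, values in per_metric.items():
                rows.append({"class": cls, "metric": metric, **aggregate(values[:, j])})
        rows.append(
            {"class": "overall", "metric": "accuracy", **aggregate(self.overall_accuracy)}
        )
        return pd.DataFrame(rows, columns=["class", "metric", "mean", "std", "ci_low", "ci_high"])


@dataclass
class ROCCurve:
    """One-vs-rest ROC sweep for a single class."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    cls: str


@dataclass
class PermutationResult:
    """Overall accuracies of the pipeline under label permutation."""

    accuracies: np.ndarray
    permutations: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if self.accuracies.size > 1 else 0.0


def confusion_and_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """3x3 confusion matrix plus per-class one-vs-rest metrics.

    Returns ``(cm, {"sensitivity": .., "specificity": .., "accuracy": ..},
    overall_accuracy)`` with per-class vectors in fixed class order.
    Per-class accuracy is one-vs-rest: (TP + TN) / n.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise EvaluationError("empty input")
    if y_true.shape != y_pred.shape:
        raise EvaluationError("length mismatch between true and predicted labels")
    bad = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not bad <= set(CLASS_LABELS):
        raise EvaluationError(f"labels outside vocabulary: {bad - set(CLASS_LABELS)}")
    cm = confusion_matrix(y_true, y_pred, labels=list(CLASS_LABELS))
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp
    metrics = {
        "sensitivity": tp / np.maximum(tp + fn, 1),
        "specificity": tn / np.maximum(tn + fp, 1),
        "accuracy": (tp + tn) / n,
    }
    overall = float(np.trace(cm) / n)
    return cm, metrics, overall


def aggregate(values: np.ndarray) -> dict[str, float]:
    """Mean, sample std, and percentile (2.5/97.5) 95% CI over repeats."""
    values = np.asarray(values, float)
    std = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    lo, hi = np.percentile(values, [2.5, 97.5]) if values.size else (np.nan, np.nan)
    return {
        "mean": float(np.mean(values)), "std": std,
        "ci_low": float(lo), "ci_high": float(hi),
    }


def roc_auc_ovr(
    decision_values: np.ndarray, y_true: np.ndarray, cls: str
) -> ROCCurve:
    """One-vs-rest ROC for ``cls`` from pooled out-of-fold decision values.

    The AUC equals the Mann-Whitney probability that a random member of the
    class scores above a random non-member (ties counting one half).
    """
    y = (np.asarray(y_true) == cls).astype(int)
    if y.min() == y.max():
        raise EvaluationError(f"AUC undefined: only one class present for {cls!r}")
    scores = np.asarray(decision_values, float)
    fpr, tpr, thr = roc_curve(y, scores)
    return ROCCurve(
        thresholds=thr, tpr=tpr, fpr=fpr,
        auc=float(roc_auc_score(y, scores)), cls=cls,
    )


def _outer_splits(
    labels: np.ndarray, config: CVConfig, repeat_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    n = labels.size
    if config.outer_scheme == "five_fold_outer":
        if config.stratified:
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=repeat_seed)
            return list(skf.split(np.zeros(n), labels))
        rng = np.random.default_rng(repeat_seed)
        order = rng.permutation(n)
        folds = np.array_split(order, 5)
        return [
            (np.setdiff1d(order, fold), fold) for fold in folds
        ]
    # repeated_holdout_80_20
    idx = np.arange(n)
    tr, te = train_test_split(
        idx, test_size=0.2, random_state=repeat_seed,
        stratify=labels if config.stratified else None,
    )
    return [(tr, te)]


def nested_cv(
    features: np.ndarray,
    labels: np.ndarray,
    config: CVConfig | None = None,
    hyper_grid: list[tuple[float, float]] | None = None,
) -> CVResult:
    """Run the dual-layer CV and collect per-repeat metrics.

    Within each repeat, every outer training portion is used to fit PCA,
    select (C, gamma) by inner stratified CV, and refit the one-vs-all
    SVMs; the corresponding held-out portion is predicted exactly once.
    All randomness derives from ``config.seed``.
    """
    config = config or CVConfig()
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    for cls in CLASS_LABELS:
        if counts.get(cls, 0) < config.inner_folds:
            raise EvaluationError(
                f"class {cls!r} has fewer members than inner_folds"
            )

    n_rep = config.repeats
    confusions = np.zeros((n_rep, 3, 3), int)
    sens = np.zeros((n_rep, 3))
    spec = np.zeros((n_rep, 3))
    acc_cls = np.zeros((n_rep, 3))
    aucs = np.zeros((n_rep, 3))
    overall = np.zeros(n_rep)

    example_true: np.ndarray | None = None
    example_decisions: np.ndarray | None = None
    root = np.random.SeedSequence(config.seed)
    for r, child in enumerate(root.spawn(n_rep)):
        repeat_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        inner_rng = np.random.default_rng(child)
        y_true_parts: list[np.ndarray] = []
        y_pred_parts: list[np.ndarray] = []
        dec_parts: list[np.ndarray] = []
        for train_idx, test_idx in _outer_splits(labels, config, repeat_seed):
            pca = pca_fit(features[train_idx], config.variance_target)
            train_scores = pca_transform(pca, features[train_idx])
            model_set = svm_train_ova(
                train_scores, labels[train_idx],
                hyper_grid=hyper_grid, inner_folds=config.inner_folds,
                rng=inner_rng, kernel=config.kernel,
            )
            pred, dec = svm_predict(model_set, pca_transform(pca, features[test_idx]))
            y_true_parts.append(labels[test_idx])
            y_pred_parts.append(pred)
            dec_parts.append(dec)
        y_true = np.concatenate(y_true_parts)
        y_pred = np.concatenate(y_pred_parts)
        decisions = np.vstack(dec_parts)
        cm, metrics, overall_acc = confusion_and_metrics(y_true, y_pred)
        confusions[r] = cm
        sens[r] = metrics["sensitivity"]
        spec[r] = metrics["specificity"]
        acc_cls[r] = metrics["accuracy"]
        overall[r] = overall_acc
        for j, cls in enumerate(CLASS_LABELS):
            aucs[r, j] = roc_auc_ovr(decisions[:, j], y_true, cls).auc
        if r == 0:
            example_true, example_decisions = y_true, decisions
    return CVResult(
        confusions=confusions, sensitivity=sens, specificity=spec,
        accuracy_class=acc_cls, auc=aucs, overall_accuracy=overall,
        example_true=example_true, example_decisions=example_decisions,
    )


def permutation_control(
    features: np.ndarray,
    labels: np.ndarray,
    config: CVConfig | None = None,
    n_permutations: int = 20,
    seed: int = 0,
    hyper_grid: list[tuple[float, float]] | None = None,
    permutations: list[np.ndarray] | None = None,
) -> PermutationResult:
    """Negative control: rerun the full nested CV with permuted labels.

    Labels are permuted uniformly at random before any model building, so
    class frequencies are preserved but label-spectrum association is
    destroyed; the whole dual-layer CV is rerun per permutation with the
    same classifier settings. Explicit ``permutations`` (index arrays)
    override the random draw, e.g. the identity permutation reproduces the
    unpermuted result exactly.
    """
    config = config or CVConfig()
    labels = np.asarray(labels)
    if permutations is None:
        if n_permutations < 1:
            raise EvaluationError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(labels.size) for _ in range(n_permutations)]
    accs = np.empty(len(permutations))
    for i, perm in enumerate(permutations):
        result = nested_cv(features, labels[perm], config, hyper_grid=hyper_grid)
        accs[i] = float(np.mean(result.overall_accuracy))
    return PermutationResult(accuracies=accs, permutations=list(permutations))


def group_spectra(
    features: np.ndarray, labels: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class channelwise mean spectrum and standard deviation."""
    labels = np.asarray(labels)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in CLASS_LABELS:
        mask = labels == cls
        if not mask.any():
            raise EvaluationError(f"no samples of class {cls!r}")
        block = np.asarray(features, float)[mask]
        out[cls] = (block.mean(axis=0), block.std(axis=0))
    return out


def difference_spectra(
    features: np.ndarray, labels: np.ndarray
) -> dict[tuple[str, str], np.ndarray]:
    """Mean-spectrum differences: cancer-normal, cancer-benign, benign-normal."""
    means = {cls: m for cls, (m, _) in group_spectra(features, labels).items()}
    pairs = [("cancer", "normal"), ("cancer", "benign"), ("benign", "normal")]
    return {(a, b): means[a] - means[b] for a, b in pairs}


__all__ = [
    "CVConfig",
    "CVResult",
    "ROCCurve",
    "PermutationResult",
    "EvaluationError",
    "confusion_and_metrics",
    "aggregate",
    "roc_auc_ovr",
    "nested_cv",
    "permutation_control",
    "group_spectra",
    "difference_spectra",
]
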