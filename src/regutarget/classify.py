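"""Signature-based subtype classification under repeated cross-validation.

A gene signature is evaluated as a molecular-subtype classifier the way
microarray-era studies did: restrict the cohort matrix to the signature
genes, run diagonal linear discriminant analysis (DLDA) or Gaussian naive
Bayes, and repeat stratified k-fold cross-validation many times, recording
the misclassification rate of each repetition and an aggregated percent
confusion matrix.

DLDA is nearest-centroid classification weighted by pooled per-gene
within-class variances (no covariance terms); with equal class priors and
class-shared variances Gaussian naive Bayes reduces to exactly the same
decision rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = ["ClassifierReport", "fit_predict_dlda", "fit_predict_nb", "cross_validate"]

_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class ClassifierReport:
    """Outcome of repeated k-fold CV of a signature classifier."""

    classifier: str
    rates: np.ndarray  # one misclassification rate per CV repetition
    confusion_percent: pd.DataFrame  # rows = true class, rows sum to 100
    n_iterations: int
    k: int
    seed: int | None
    signature: tuple[str, ...] = field(default_factory=tuple)

    @property
    def median_rate(self) -> float:
        return float(np.median(self.rates))

    def to_json_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "rates": self.rates.tolist(),
            "confusion_percent": self.confusion_percent.to_dict(),
            "n_iterations": self.n_iterations,
            "k": self.k,
            "seed": self.seed,
        }


def _check_training(y: np.ndarray) -> tuple[np.ndarray, list]:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain >= 2 classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"classes with < 2 training samples: {small.tolist()}")
    return classes, counts


def fit_predict_dlda(
    x_train: np.ndarray, y_train, x_test: np.ndarray
) -> np.ndarray:
    """Diagonal LDA: argmin_c sum_j (x_j - mu_cj)^2 / s_j^2.

    ``s_j^2`` is the pooled within-class variance per gene, floored at
    1e-8.  Ties go to the first class in sorted label order.
    """
    x_train, x_test = np.asarray(x_train, float), np.asarray(x_test, float)
    y_train = np.asarray(y_train)
    classes, _ = _check_training(y_train)
    n, _ = x_train.shape
    mus = np.stack([x_train[y_train == c].mean(axis=0) for c in classes])
    ss = np.zeros(x_train.shape[1])
    for ci, c in enumerate(classes):
        xc = x_train[y_train == c]
        ss += ((xc - mus[ci]) ** 2).sum(axis=0)
    s2 = np.maximum(ss / (n - classes.size), _VAR_FLOOR)
    # distance of every test sample to every class centroid
    d2 = (((x_test[:, None, :] - mus[None, :, :]) ** 2) / s2).sum(axis=2)
    return classes[np.argmin(d2, axis=1)]  # argmin -> first (sorted) class on ties


def fit_predict_nb(x_train: np.ndarray, y_train, x_test: np.ndarray) -> np.ndarray:
    """Gaussian naive Bayes with class-specific per-gene variances.

    Variances floored at 1e-8; empirical class priors; maximum log
    posterior, ties to the first class in sorted label order.
    """
    x_train, x_test = np.asarray(x_train, float), np.asarray(x_test, float)
    y_train = np.asarray(y_train)
    classes, counts = _check_training(y_train)
    log_post = np.empty((x_test.shape[0], classes.size))
    for ci, c in enumerate(classes):
        xc = x_train[y_train == c]
        mu = xc.mean(axis=0)
        var = np.maximum(xc.var(axis=0), _VAR_FLOOR)
        ll = -0.5 * (np.log(2 * np.pi * var) + (x_test - mu) ** 2 / var).sum(axis=1)
        log_post[:, ci] = ll + np.log(counts[ci] / y_train.size)
    return classes[np.argmax(log_post, axis=1)]


_CLASSIFIERS = {"dlda": fit_predict_dlda, "naive_bayes": fit_predict_nb}


def cross_validate(
    cohort: pd.DataFrame,
    labels: pd.Series,
    signature,
    classifier: str = "dlda",
    k: int = 10,
    iterations: int = 100,
    seed: int | None = None,
    max_retries: int = 10,
) -> ClassifierReport:
    """Repeated stratified k-fold CV of a signature classifier.

    ``cohort`` is samples x genes; signature genes absent from the cohort
    are dropped with a warning.  Each iteration reshuffles the stratified
    folds; its misclassification rate pools errors across the k folds.
    The confusion matrix aggregates raw counts over all iterations and is
    then row-normalised to percent.  If a fold leaves a class absent from
    training, the iteration is reshuffled (up to ``max_retries``).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if classifier not in _CLASSIFIERS:
        raise ValueError(f"classifier must be one of {sorted(_CLASSIFIERS)}")
    labels = labels.loc[cohort.index]
    if labels.isna().any():
        raise ValueError("missing subtype labels")
    sig = list(dict.fromkeys(signature))
    present = [g for g in sig if g in cohort.columns]
    dropped = sorted(set(sig) - set(present))
    if dropped:
        warnings.warn(f"{len(dropped)} signature genes absent from cohort, dropped: {dropped[:5]}")
    if not present:
        raise ValueError("no signature genes present in the cohort matrix")

    x = cohort[present].to_numpy(dtype=float)
    y = labels.to_numpy()
    classes = np.unique(y)
    predict = _CLASSIFIERS[classifier]
    rng = np.random.default_rng(seed)
    class_idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    rates = np.empty(iterations)

    for it in range(iterations):
        for attempt in range(max_retries):
            splitter = StratifiedKFold(
                n_splits=k, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
            )
            folds = list(splitter.split(x, y))
            if all(np.unique(y[tr]).size == classes.size for tr, _ in folds):
                break
        else:
            raise RuntimeError("could not build folds with every class in training")
        errors = 0
        for tr, te in folds:
            pred = predict(x[tr], y[tr], x[te])
            errors += int((pred != y[te]).sum())
            for t_lab, p_lab in zip(y[te], pred):
                confusion[class_idx[t_lab], class_idx[p_lab]] += 1
        rates[it] = errors / y.size

    row_sums = confusion.sum(axis=1, keepdims=True)
    percent = 100.0 * confusion / np.maximum(row_sums, 1)
    conf_df = pd.DataFrame(percent, index=classes, columns=classes)
    conf_df.index.name, conf_df.columns.name = "true", "predicted"
    return ClassifierReport(
        classifier, rates, conf_df, iterations, k, seed, tuple(present)
    )
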