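"""Pairwise SVM decoding over time and temporal generalization.

For each time point a linear support-vector machine (C = 1) is trained to
separate two conditions from the sensor pattern across channels, under
k-fold leave-one-group-out cross-validation repeated with reshuffled fold
assignments.  Features are standardized per time point using training-fold
statistics only.  Classifier weights are converted to activation patterns
via the training-data covariance (pattern = S_X w), which is what admits a
physiological interpretation; raw weights do not.

Temporal generalization trains at one time point and tests at all others,
probing whether the discriminative pattern is stable over time.
Group-level significance versus the 50% chance level is assessed with
:func:`seqmeg.stats.test_vs_chance` (one-sided signed-rank across subjects).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.svm import SVC

from .datatypes import DecodingResult, SensorEpochs
from .stats import test_vs_chance  # noqa: F401  (re-export: part of this API)

__all__ = ["decode_timecourse", "temporal_generalization", "test_vs_chance"]


def _extract_pair(epochs: SensorEpochs, label_a: str, label_b: str):
    ia = np.flatnonzero(epochs.labels == label_a)
    ib = np.flatnonzero(epochs.labels == label_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"missing trials for pair ({label_a}, {label_b})")
    if not 0.5 <= len(ia) / len(ib) <= 2.0:
        warnings.warn("class imbalance beyond 2:1", stacklevel=3)
    X = np.concatenate([epochs.data[ia], epochs.data[ib]], axis=0)
    y = np.concatenate([np.zeros(len(ia)), np.ones(len(ib))])
    return X, y


def _fold_assignment(y: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Stratified random fold ids: each class spread evenly over folds."""
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls} has fewer trials ({len(idx)}) than folds")
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((x - mu) / sd for x in (train, *others))


def decode_timecourse(epochs: SensorEpochs,
                      label_a: str,
                      label_b: str,
                      n_folds: int = 5,
                      n_reps: int = 100,
                      rng: np.random.Generator | int | None = 0,
                      compute_patterns: bool = True,
                      C: float = 1.0) -> DecodingResult:
    """Time-resolved pairwise decoding accuracy for one subject.

    Per time point and repetition, a linear SVM is trained on n_folds - 1
    trial groups and tested on the held-out group, cycling over folds;
    accuracies are averaged over folds and the ``n_reps`` reshuffled fold
    assignments.  Activation patterns (channels x time) are averaged the
    same way when ``compute_patterns`` is set.
    """
    X, y = _extract_pair(epochs, label_a, label_b)
    rng = np.random.default_rng(rng)
    n_trials, n_channels, n_times = X.shape
    acc = np.zeros(n_times)
    patterns = np.zeros((n_channels, n_times)) if compute_patterns else None
    n_models = 0
    for _ in range(n_reps):
        folds = _fold_assignment(y, n_folds, rng)
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            y_tr, y_te = y[tr], y[te] > 0
            # standardize every time point at once with training statistics,
            # then hand the classifier contiguous time-major slices
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = np.ascontiguousarray(
                ((X[tr] - mu) / sd).transpose(2, 0, 1))
            Xte = np.ascontiguousarray(
                ((X[te] - mu) / sd).transpose(2, 0, 1))
            for t in range(n_times):
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xtr[t], y_tr)
                w, b = clf.coef_[0], clf.intercept_[0]
                acc[t] += np.mean((Xte[t] @ w + b > 0) == y_te)
                if compute_patterns:
                    cov = np.cov(Xtr[t], rowvar=False)
                    patterns[:, t] += cov @ w
        n_models += n_folds
    acc /= n_models
    if compute_patterns:
        patterns /= n_models
    return DecodingResult(accuracy=acc, patterns=patterns, tg_matrix=None,
                          n_folds=n_folds, n_reps=n_reps,
                          pair=(label_a, label_b))


def temporal_generalization(epochs: SensorEpochs,
                            label_a: str,
                            label_b: str,
                            n_folds: int = 5,
                            n_reps: int = 10,
                            rng: np.random.Generator | int | None = 0,
                            C: float = 1.0) -> np.ndarray:
    """Train-time x test-time accuracy matrix (same CV as the time course).

    The classifier trained at each time point scores the held-out trials at
    every time point; the diagonal reproduces :func:`decode_timecourse` up
    to Monte-Carlo error.
    """
    X, y = _extract_pair(epochs, label_a, label_b)
    rng = np.random.default_rng(rng)
    n_trials, n_channels, n_times = X.shape
    tg = np.zeros((n_times, n_times))
    n_models = 0
    sign = np.where(y == 0, -1.0, 1.0)  # class 1 = positive decision side
    for _ in range(n_reps):
        folds = _fold_assignment(y, n_folds, rng)
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            y_tr = y[tr]
            sign_te = sign[te]
            # the scaler fitted at the training time point is applied to the
            # held-out trials at every test time point
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = np.ascontiguousarray(
                ((X[tr] - mu) / sd).transpose(2, 0, 1))
            for t in range(n_times):
                Xte_t = (X[te] - mu[:, t, None]) / sd[:, t, None]
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xtr[t], y_tr)
                w, b = clf.coef_[0], clf.intercept_[0]
                scores = np.einsum("c,ncm->nm", w, Xte_t) + b
                tg[t] += np.mean((scores > 0) == (sign_te[:, None] > 0),
                                 axis=0)
        n_models += n_folds
    return tg / n_models
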