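"""Logistic-regression and SVM baselines on per-trial summary features.

Both classifiers see the same five aggregates (number of fixations, mean and
SD of fixation duration in ms, mean and SD of saccade length in px),
z-scored internally, so they are invariant to affine rescaling of any input
feature. The logistic model is effectively unpenalized (a tiny L2 term keeps
the solver stable); the SVM uses an RBF kernel with C = 1 by default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import ObservationSequence, SummaryFeatures, summary_features

__all__ = [
    "FEATURE_NAMES",
    "feature_matrix",
    "fit_logistic",
    "fit_svm",
    "SummaryClassifier",
    "LogisticBaseline",
    "SvmBaseline",
]

FEATURE_NAMES = SummaryFeatures.FEATURE_NAMES


def feature_matrix(seqs: Sequence[ObservationSequence]) -> tuple[np.ndarray, list[str]]:
    """(n_trials, 5) summary-feature matrix and the strategy labels."""
    X = np.stack([summary_features(s).as_array() for s in seqs])
    y = [s.strategy for s in seqs]
    return X, y


def _check_labels(y) -> None:
    if len(set(y)) < 2:
        raise ValueError("training data must contain both strategy classes")


def fit_logistic(X: np.ndarray, y: Sequence[str]) -> Pipeline:
    """Standardized, (near-)unpenalized logistic regression."""
    _check_labels(y)
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=1e6, max_iter=2000)),
        ]
    )
    clf.fit(X, list(y))
    return clf


def fit_svm(X: np.ndarray, y: Sequence[str], *, kernel: str = "rbf",
            C: float = 1.0, gamma: str | float = "scale") -> Pipeline:
    """Standardized support-vector classifier (RBF by default)."""
    _check_labels(y)
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, gamma=gamma)),
        ]
    )
    clf.fit(X, list(y))
    return clf


class SummaryClassifier:
    """Shared fit/predict surface over observation sequences."""

    def __init__(self):
        self.model_: Pipeline | None = None

    def _fit_matrix(self, X: np.ndarray, y: Sequence[str]) -> Pipeline:
        raise NotImplementedError

    def fit(self, seqs: Sequence[ObservationSequence], labels: Sequence[str] | None = None):
        X, y = feature_matrix(seqs)
        if labels is not None:
            y = list(labels)
        self.model_ = self._fit_matrix(X, y)
        return self

    def predict(self, seqs: Sequence[ObservationSequence]) -> list[str]:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        X, _ = feature_matrix(seqs)
        return list(self.model_.predict(X))


class LogisticBaseline(SummaryClassifier):
    def _fit_matrix(self, X, y):
        return fit_logistic(X, y)


class SvmBaseline(SummaryClassifier):
    def __init__(self, *, kernel: str = "rbf", C: float = 1.0, gamma="scale"):
        super().__init__()
        self.kernel = kernel
        self.C = C
        self.gamma = gamma

    def _fit_matrix(self, X, y):
        return fit_svm(X, y, kernel=self.kernel, C=self.C, gamma=self.gamma)
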