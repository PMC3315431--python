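"""Classifiers producing a per-document confidence of being 'useful'.

Four supervised algorithms are supported — logistic regression, k-nearest
neighbours, naive Bayes and a Gaussian-kernel SVM — all consuming a
DocTermMatrix and labels, and all exposing one contract: a real-valued
confidence per document, higher meaning more likely 'useful'. Ranking by
confidence, not hard labeling, is the primary output.

Confidence semantics per algorithm:

* SVM — signed decision-function value (distance from the hyperplane,
  positive side = useful); no probability calibration since only the
  ranking is consumed.
* logistic regression / naive Bayes — posterior probability of 'useful'.
* k-NN — fraction of the k neighbours labeled 'useful'.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .corpus_io import NON_USEFUL, USEFUL, ValidationError
from .features import TFIDF, DocTermMatrix

logger = logging.getLogger(__name__)

LOGISTIC_REGRESSION = "logistic_regression"
KNN = "knn"
NAIVE_BAYES = "naive_bayes"
SVM = "svm"
ALGORITHMS = (LOGISTIC_REGRESSION, KNN, NAIVE_BAYES, SVM)


@dataclass(frozen=True)
class ModelConfig:
    """Algorithm choice plus the hyperparameters that algorithm consults.

    ``gamma`` may be a positive float or the string 'scale' (kernel width
    1/(n_features * Var(X)), robust to the feature magnitude differences
    between weightings). ``C = 0`` is accepted as a legacy sentinel for
    "choose automatically" and mapped to the default 1.0 with a warning;
    a literal zero soft-margin penalty is undefined.
    """

    algorithm: str = SVM
    k: int = 3
    gamma: float | str = "scale"
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.k < 1 or self.k % 2 == 0:
            raise ValidationError("k must be an odd integer >= 1")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise ValidationError("gamma must be a positive number or 'scale'")
        elif self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if self.C == 0:
            logger.warning("C = 0 interpreted as 'choose automatically'; using C = 1.0")
            object.__setattr__(self, "C", 1.0)
        if self.C < 0:
            raise ValidationError("C must be > 0")


@dataclass(frozen=True)
class Prediction:
    doc_id: str
    confidence: float
    label: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.confidence):
            raise ValidationError(f"non-finite confidence for {self.doc_id!r}")


@dataclass(frozen=True)
class TrainedModel:
    config: ModelConfig
    estimator: object = field(repr=False)
    terms: tuple[str, ...]
    weighting: str
    class_prior: float  # useful fraction of the training labels

    @property
    def decision_threshold(self) -> float:
        return 0.0 if self.config.algorithm == SVM else 0.5


def gaussian_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2): 1 iff x == y, symmetric, in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    diff = x - y
    return float(np.exp(-gamma * float(diff @ diff)))


def _encode_labels(labels: list[str]) -> np.ndarray:
    y = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab == USEFUL:
            y[i] = 1
        elif lab == NON_USEFUL:
            y[i] = 0
        else:
            raise ValidationError(f"unlabeled document at position {i}")
    return y


def train(
    matrix: DocTermMatrix, labels: list[str], config: ModelConfig
) -> TrainedModel:
    """Fit the configured classifier on a weighted matrix.

    Both classes must be present. Naive Bayes is multinomial on count-like
    weightings and Gaussian on TF-IDF (continuous proportions). Fitting is
    deterministic given the config seed.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("empty matrix")
    if matrix.shape[0] != len(labels):
        raise ValidationError(
            f"{matrix.shape[0]} rows but {len(labels)} labels"
        )
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError(
            "training labels contain a single class; both 'useful' and "
            "'non-useful' examples are required"
        )
    algo = config.algorithm
    if algo == SVM:
        estimator = SVC(kernel="rbf", gamma=config.gamma, C=config.C)
    elif algo == LOGISTIC_REGRESSION:
        estimator = LogisticRegression(max_iter=2000)
    elif algo == KNN:
        if config.k > len(labels):
            raise ValidationError("k exceeds the number of training documents")
        estimator = KNeighborsClassifier(n_neighbors=config.k)
    else:  # naive Bayes, variant chosen by weighting
        estimator = GaussianNB() if matrix.weighting == TFIDF else MultinomialNB()
    estimator.fit(matrix.values, y)
    return TrainedModel(
        config=config,
        estimator=estimator,
        terms=matrix.terms,
        weighting=matrix.weighting,
        class_prior=float(np.mean(y)),
    )


def score(model: TrainedModel, matrix: DocTermMatrix) -> list[Prediction]:
    """One Prediction per matrix row, in row order."""
    if matrix.terms != model.terms:
        raise ValidationError(
            "matrix term order differs from the model's training order; "
            "use transform_new on the fitted matrix"
        )
    if model.config.algorithm == SVM:
        confidences = model.estimator.decision_function(matrix.values)
    else:
        proba = model.estimator.predict_proba(matrix.values)
        col = int(np.where(model.estimator.classes_ == 1)[0][0])
        confidences = proba[:, col]
    threshold = model.decision_threshold
    return [
        Prediction(
            doc_id=doc_id,
            confidence=float(c),
            label=USEFUL if c >= threshold else NON_USEFUL,
        )
        for doc_id, c in zip(matrix.doc_ids, confidences)
    ]


_PERSIST_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {"version": _PERSIST_VERSION, "model": model}
    with open(path, "wb") as out:
        pickle.dump(payload, out)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as handle:
        payload = pickle.load(handle)
    if payload.get("version") != _PERSIST_VERSION:
        raise ValidationError(f"unsupported model archive version: {payload.get('version')}")
    return payload["model"]
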