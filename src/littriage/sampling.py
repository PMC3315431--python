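"""Training-set selection: Kennard-Stone and confidence-extremes.

Kennard-Stone picks maximally mutually dissimilar documents: the first two
selections are the pair at maximal Euclidean distance, and each further
selection maximizes its minimum distance to everything already selected.
It is the selection the specific system uses to choose the handful of
documents a human will label.

Confidence-extremes instead takes the documents a general system is most
and least confident about — the proposed remedy when Kennard-Stone returns
a single-class or badly imbalanced selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .corpus_io import ValidationError
from .features import DocTermMatrix
from .models import Prediction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Selected row indices in selection order plus per-step distances.

    ``distances[0]`` and ``distances[1]`` both record the maximal pairwise
    distance that seeded the selection; thereafter each entry is the
    min-distance-to-selected of the chosen point, a non-increasing series.
    """

    indices: tuple[int, ...]
    distances: tuple[float, ...]
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValidationError("selected indices must be unique")


def kennard_stone(matrix: DocTermMatrix, n_select: int) -> SelectionResult:
    """Max-min (Kennard-Stone) selection of ``n_select`` document rows.

    Distance ties break toward the lowest row index. If every row is
    identical the selection degenerates to index order (warned).
    """
    n = matrix.shape[0]
    if not (2 <= n_select <= n):
        raise ValidationError(
            f"n_select must be in [2, {n}], got {n_select}"
        )
    dist = cdist(matrix.values, matrix.values)
    if np.all(dist == 0):
        logger.warning(
            "all documents identical under the metric; selecting by index order"
        )
    # seed pair: maximal pairwise distance, lexicographically first on ties
    flat = np.argmax(dist)  # row-major argmax = lowest (i, j) among ties
    i, j = np.unravel_index(flat, dist.shape)
    if i == j:  # all-zero distance matrix
        i, j = 0, 1
    selected = [int(min(i, j)), int(max(i, j))]
    distances = [float(dist[i, j]), float(dist[i, j])]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))  # argmax takes lowest index on ties
        selected.append(nxt)
        distances.append(float(min_dist[nxt]))
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return SelectionResult(tuple(selected), tuple(distances))


def confidence_extremes(
    predictions: list[Prediction], n_select: int
) -> list[str]:
    """Doc ids of the top and bottom ``n_select/2`` by confidence.

    Takes the documents the ranking model is most confident are useful and
    most confident are not, to favour getting both classes into a small
    manual-labeling budget.
    """
    if not predictions:
        raise ValidationError("no predictions to select from")
    if n_select % 2 != 0:
        raise ValidationError("n_select must be even")
    if n_select > len(predictions):
        raise ValidationError(
            f"n_select {n_select} exceeds population {len(predictions)}"
        )
    ordered = sorted(predictions, key=lambda p: (-p.confidence, p.doc_id))
    half = n_select // 2
    top = [p.doc_id for p in ordered[:half]]
    bottom = [p.doc_id for p in ordered[len(ordered) - half :]]
    return top + bottom
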