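"""Ranking performance: AUC and lift charts.

AUC is the probability that a randomly chosen useful document receives a
higher confidence than a randomly chosen non-useful one; it is computed
exactly via the Mann-Whitney rank-sum statistic with midrank tie handling
(ties contribute half credit), in O(n log n).

A lift chart bins the confidence-ranked list into near-equal deciles and
reports, per bin, how many useful documents it contains and the cumulative
percentage of all useful documents recovered so far, against the diagonal
a random ordering would give.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .corpus_io import NON_USEFUL, USEFUL, ValidationError


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    y = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab == USEFUL:
            y[i] = 1
        elif lab == NON_USEFUL:
            y[i] = 0
        else:
            raise ValidationError(f"unlabeled document at position {i}")
    return y


def auc(confidences: Sequence[float], labels: Sequence[str]) -> float:
    """Probability a useful document outranks a non-useful one.

    Equals [#(useful above non-useful) + 0.5 * ties] / (n_u * n_n),
    computed via midranks.
    """
    scores = np.asarray(confidences, dtype=float)
    if len(scores) != len(labels):
        raise ValidationError("confidences and labels differ in length")
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass(frozen=True)
class LiftCurve:
    """Decile summary of a confidence-ranked labeled list.

    ``presented[b]`` documents fall in bin b (largest-remainder sizing,
    extra documents in the earliest bins); ``useful[b]`` of them are
    useful; ``cumulative_pct[b]`` is 100 x (useful in bins 0..b) / total
    useful; ``baseline_pct`` is the random-ranking diagonal.
    """

    n_bins: int
    presented: tuple[int, ...]
    useful: tuple[int, ...]
    cumulative_pct: tuple[float, ...]
    baseline_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.presented) != self.n_bins:
            raise ValidationError("per-bin arrays must have n_bins entries")

    @property
    def total_useful(self) -> int:
        return sum(self.useful)

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "presented": list(self.presented),
            "useful": list(self.useful),
            "cumulative_pct": list(self.cumulative_pct),
            "baseline_pct": list(self.baseline_pct),
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            out.write("bin\tpresented\tuseful\tcumulative_pct\tbaseline_pct\n")
            for b in range(self.n_bins):
                out.write(
                    f"{b + 1}\t{self.presented[b]}\t{self.useful[b]}\t"
                    f"{self.cumulative_pct[b]:.4f}\t{self.baseline_pct[b]:.4f}\n"
                )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def plot(self, ax=None):
        """Render bars (useful per bin) + cumulative and baseline lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, self.n_bins + 1)
        ax.bar(x, self.useful, color="firebrick", alpha=0.7, label="useful per bin")
        ax2 = ax.twinx()
        ax2.plot(x, self.cumulative_pct, marker="o", label="model ranking")
        ax2.plot(x, self.baseline_pct, color="black", label="random baseline")
        ax.set_xlabel(f"bin (each ~{100 // self.n_bins}% of articles)")
        ax.set_ylabel("useful articles in bin")
        ax2.set_ylabel("cumulative % of useful articles")
        ax2.legend(loc="lower right")
        return ax


def lift_curve(
    confidences: Sequence[float],
    labels: Sequence[str],
    n_bins: int = 10,
    doc_ids: Sequence[str] | None = None,
) -> LiftCurve:
    """Build a lift curve from confidences and labels.

    Documents are sorted by confidence descending (ties by doc_id
    ascending when ids are given, else by position); bin sizes differ by
    at most one, extras in the first bins.
    """
    n = len(confidences)
    if n == 0:
        raise ValidationError("empty input")
    if n_bins < 1 or n < n_bins:
        raise ValidationError("need n_bins >= 1 and at least n_bins documents")
    y = _as_binary(labels)
    if doc_ids is None:
        order = sorted(range(n), key=lambda i: (-confidences[i], i))
    else:
        order = sorted(range(n), key=lambda i: (-confidences[i], doc_ids[i]))
    ranked = y[np.asarray(order)]
    base, extra = divmod(n, n_bins)
    sizes = [base + 1 if b < extra else base for b in range(n_bins)]
    presented, useful = [], []
    start = 0
    for size in sizes:
        presented.append(size)
        useful.append(int(ranked[start : start + size].sum()))
        start += size
    total_useful = int(y.sum())
    if total_useful == 0:
        raise ValidationError("no useful documents; lift curve undefined")
    cum = np.cumsum(useful) / total_useful * 100.0
    baseline = [100.0 * (b + 1) / n_bins for b in range(n_bins)]
    return LiftCurve(
        n_bins=n_bins,
        presented=tuple(presented),
        useful=tuple(useful),
        cumulative_pct=tuple(float(c) for c in cum),
        baseline_pct=tuple(baseline),
    )
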