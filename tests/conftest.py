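"""Shared fixtures: random term-count fixtures and tiny corpora."""

from __future__ import annotations

import numpy as np
import pytest

from littriage.corpus_io import NON_USEFUL, USEFUL, Corpus, Document
from littriage.text_processing import (
    GENERAL,
    SPECIFIC,
    LexiconEntry,
    PredictorLexicon,
    TermCounts,
)


def random_counts_fixture(
    rng: np.random.Generator,
    n_docs: int,
    n_terms: int,
    density: float = 0.3,
    max_count: int = 6,
) -> tuple[TermCounts, PredictorLexicon]:
    """A random, mutually consistent (TermCounts, PredictorLexicon) pair.

    Every lexicon term occurs in at least one document; document token
    totals include extra off-lexicon tokens so TF denominators exceed the
    counted sums (as after document-frequency pruning).
    """
    terms = [f"term{i:03d}" for i in range(n_terms)]
    occ = (rng.random((n_docs, n_terms)) < density) * rng.integers(
        1, max_count + 1, size=(n_docs, n_terms)
    )
    # ensure every term occurs somewhere (lexicon invariant: n_i >= 1)
    for j in range(n_terms):
        if not occ[:, j].any():
            occ[rng.integers(n_docs), j] = rng.integers(1, max_count + 1)
    doc_ids = tuple(f"d{i:04d}" for i in range(n_docs))
    counts = tuple(
        {terms[j]: int(occ[i, j]) for j in range(n_terms) if occ[i, j]}
        for i in range(n_docs)
    )
    extra = rng.integers(0, 10, size=n_docs)
    totals = tuple(int(occ[i].sum() + extra[i]) for i in range(n_docs))
    lexicon = PredictorLexicon(
        tuple(
            LexiconEntry(
                term=terms[j],
                category=GENERAL if rng.random() < 0.5 else SPECIFIC,
                document_frequency=int((occ[:, j] > 0).sum()),
            )
            for j in range(n_terms)
        )
    )
    return TermCounts(doc_ids, counts, totals), lexicon


@pytest.fixture
def toy_corpus() -> Corpus:
    """Six short labeled documents with an obvious 'useful' vocabulary."""
    docs = [
        Document("1", "Serious adverse event after infliximab",
                 "A fatal adverse reaction with safety concerns.", USEFUL),
        Document("2", "Adverse drug reaction report",
                 "Safety monitoring found a serious adverse event.", USEFUL),
        Document("3", "Pharmacokinetics of etanercept",
                 "Absorption and distribution were studied.", NON_USEFUL),
        Document("4", "Cost effectiveness analysis",
                 "Economic burden of biologic therapy.", NON_USEFUL),
        Document("5", "Dosing schedule comparison",
                 "Weekly versus biweekly administration outcomes.", NON_USEFUL),
        Document("6", "Risk of serious infection",
                 "Adverse events and mortality were reported.", USEFUL),
    ]
    return Corpus(docs, provenance="toy")
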