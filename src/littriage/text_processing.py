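"""The mining chain: tokenize -> stem -> stop words -> synonyms -> phrases.

Every document's title + abstract passes through this fixed chain, after
which per-document term counts feed the feature weightings. Predictors are
the chain's surviving terms, pruned by a minimum document frequency and
partitioned into *general* (drug-class-agnostic) and *specific* categories
by membership in the resource set's general-term list.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_io import Corpus, ValidationError
from .resources import ResourceSet
from .stemming import stem as porter_stem

# maximal runs of letters/digits (unicode); underscore excluded so that it
# can safely join phrase terms later
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens, punctuation stripped, order kept.

    Hyphenated forms split into their components; tokens that are pure
    digits are dropped (numbers carry no predictor signal here); Greek
    letters survive as single-character tokens.
    """
    return [t for t in _TOKEN_RE.findall(text.lower()) if not t.isdigit()]


def stem(token: str) -> str:
    """Porter root of a token (idempotent; see :mod:`littriage.stemming`)."""
    return porter_stem(token)


def remove_stopwords(tokens: Sequence[str], stopwords: Iterable[str]) -> list[str]:
    stopset = set(stopwords)
    return [t for t in tokens if t not in stopset]


def merge_synonyms(tokens: Sequence[str], synonyms: dict[str, str]) -> list[str]:
    """Replace each token by its canonical form where the map covers it."""
    for variant, canonical in synonyms.items():
        target = synonyms.get(canonical)
        if target is not None and target != canonical:
            raise ValidationError(
                f"synonym chain: {variant!r} -> {canonical!r} -> {target!r}"
            )
    return [synonyms.get(t, t) for t in tokens]


def detect_phrases(
    tokens: Sequence[str], phrases: Iterable[Sequence[str]]
) -> list[str]:
    """Join known multiword terms into single underscore-joined tokens.

    Matching is leftmost and maximal: at each position the longest phrase
    starting there wins, matched spans do not overlap, and unmatched tokens
    pass through unchanged.
    """
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for phrase in phrases:
        phrase = tuple(phrase)
        by_first.setdefault(phrase[0], []).append(phrase)
    for candidates in by_first.values():
        candidates.sort(key=len, reverse=True)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        token = tokens[i]
        matched = False
        for phrase in by_first.get(token, ()):
            k = len(phrase)
            if i + k <= n and tuple(tokens[i : i + k]) == phrase:
                out.append("_".join(phrase))
                i += k
                matched = True
                break
        if not matched:
            out.append(token)
            i += 1
    return out


def process_text(
    text: str, resources: ResourceSet, use_stemming: bool = True
) -> list[str]:
    """Run the full chain on one document's text, returning final terms."""
    tokens = tokenize(text)
    if use_stemming:
        tokens = [stem(t) for t in tokens]
    tokens = remove_stopwords(tokens, resources.stopwords)
    tokens = merge_synonyms(tokens, resources.synonyms)
    tokens = detect_phrases(tokens, resources.phrases)
    return tokens


GENERAL = "general"
SPECIFIC = "specific"


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    category: str  # general | specific
    document_frequency: int


@dataclass(frozen=True)
class PredictorLexicon:
    """Extracted predictor terms with category and document frequency n_i."""

    entries: tuple[LexiconEntry, ...]

    def __post_init__(self) -> None:
        terms = [e.term for e in self.entries]
        if len(set(terms)) != len(terms):
            raise ValidationError("duplicate terms in lexicon")
        for e in self.entries:
            if e.category not in (GENERAL, SPECIFIC):
                raise ValidationError(f"bad category {e.category!r}")
            if e.document_frequency < 1:
                raise ValidationError(
                    f"term {e.term!r} has document_frequency < 1"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def terms(self) -> list[str]:
        return [e.term for e in self.entries]

    @property
    def document_frequencies(self) -> dict[str, int]:
        return {e.term: e.document_frequency for e in self.entries}

    @property
    def categories(self) -> dict[str, str]:
        return {e.term: e.category for e in self.entries}


@dataclass(frozen=True)
class TermCounts:
    """Per-document occurrence counts n_i,j plus pre-pruning token totals.

    ``counts`` holds only lexicon terms; ``totals`` is the sum over *all*
    chain-surviving terms of the document (the TF denominator), recorded
    before document-frequency pruning so TF stays a true within-document
    proportion.
    """

    doc_ids: tuple[str, ...]
    counts: tuple[dict[str, int], ...]
    totals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.doc_ids) == len(self.counts) == len(self.totals)):
            raise ValidationError("TermCounts fields must have equal length")
        for doc_id, c, total in zip(self.doc_ids, self.counts, self.totals):
            doc_sum = sum(c.values())
            if doc_sum > total:
                raise ValidationError(
                    f"document {doc_id!r}: counted terms exceed token total"
                )
            if any(v < 1 for v in c.values()):
                raise ValidationError(f"document {doc_id!r}: non-positive count")

    def __len__(self) -> int:
        return len(self.doc_ids)

    def restrict(self, terms: Iterable[str]) -> "TermCounts":
        """Keep only the given terms in each document's counts."""
        keep = set(terms)
        return TermCounts(
            doc_ids=self.doc_ids,
            counts=tuple(
                {t: n for t, n in c.items() if t in keep} for c in self.counts
            ),
            totals=self.totals,
        )


def count_corpus(
    corpus: Corpus, resources: ResourceSet, use_stemming: bool = True
) -> TermCounts:
    """Raw chain output for each document: all surviving terms counted."""
    doc_ids, counts, totals = [], [], []
    for doc in corpus:
        terms = process_text(doc.text, resources, use_stemming)
        counter = Counter(terms)
        doc_ids.append(doc.doc_id)
        counts.append(dict(counter))
        totals.append(len(terms))
    return TermCounts(tuple(doc_ids), tuple(counts), tuple(totals))


def extract_predictors(
    corpus: Corpus,
    resources: ResourceSet,
    min_document_frequency: int = 2,
    use_stemming: bool = True,
) -> tuple[PredictorLexicon, TermCounts]:
    """Run the chain over a corpus and build the predictor lexicon.

    Terms appearing in fewer than ``min_document_frequency`` documents are
    pruned (default 2: singleton terms dropped). Each surviving term is
    categorized *general* if it is in the resource set's general-term list,
    else *specific*.
    """
    if len(corpus) == 0:
        raise ValidationError("extract_predictors requires a non-empty corpus")
    raw = count_corpus(corpus, resources, use_stemming)
    doc_freq: Counter[str] = Counter()
    for c in raw.counts:
        doc_freq.update(c.keys())
    kept = {t for t, df in doc_freq.items() if df >= min_document_frequency}
    if not kept:
        raise ValidationError(
            f"no term reaches document frequency {min_document_frequency}; "
            "lower min_document_frequency"
        )
    entries = tuple(
        LexiconEntry(
            term=t,
            category=GENERAL if t in resources.general_terms else SPECIFIC,
            document_frequency=doc_freq[t],
        )
        for t in sorted(kept)
    )
    return PredictorLexicon(entries), raw.restrict(kept)


def restrict_general(lexicon: PredictorLexicon) -> PredictorLexicon:
    """Keep only general-category predictors (the general system's lexicon)."""
    entries = tuple(e for e in lexicon.entries if e.category == GENERAL)
    if not entries:
        raise ValidationError("no general predictors in lexicon")
    return PredictorLexicon(entries)
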