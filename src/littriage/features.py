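"""Feature weightings for the document x predictor matrix.

Three weightings are supported, matching the comparison the systems run:

* occurrence — raw count n_i,j of predictor i in document j
* binary     — presence indicator 1[n_i,j >= 1]
* tfidf      — TF_i,j * IDF_i with
               TF_i,j = n_i,j / sum_k n_k,j   (within-document proportion)
               IDF_i  = log(N / n_i)          (N documents fitted, n_i the
                                               number containing term i)

The TF denominator is the document's full chain-token total; the logarithm
base defaults to 10 (a positive scalar on all features; configurable). The
IDF table is fitted once on the training corpus and frozen: unseen
documents are weighted with the stored table via :func:`transform_new`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .corpus_io import ValidationError
from .text_processing import PredictorLexicon, TermCounts

OCCURRENCE = "occurrence"
BINARY = "binary"
TFIDF = "tfidf"
WEIGHTINGS = (OCCURRENCE, BINARY, TFIDF)


@dataclass(frozen=True)
class DocTermMatrix:
    doc_ids: tuple[str, ...]
    terms: tuple[str, ...]
    values: np.ndarray  # shape (n_docs, n_terms), non-negative
    weighting: str
    idf_table: np.ndarray | None = None  # per-term IDF_i, tfidf only
    n_fit: int | None = None  # document count the IDF was fitted on
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.weighting not in WEIGHTINGS:
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if self.values.shape != (len(self.doc_ids), len(self.terms)):
            raise ValidationError("values shape does not match ids/terms")
        if np.any(self.values < 0):
            raise ValidationError("negative feature value")
        if self.weighting == TFIDF:
            if self.idf_table is None or self.n_fit is None:
                raise ValidationError("tfidf matrix requires idf_table and n_fit")
            if not np.all(np.isfinite(self.idf_table)) or np.any(self.idf_table < 0):
                raise ValidationError("idf_table must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _expand(counts: TermCounts, lexicon: PredictorLexicon) -> np.ndarray:
    terms = lexicon.terms
    index = {t: i for i, t in enumerate(terms)}
    out = np.zeros((len(counts), len(terms)))
    for row, doc_counts in enumerate(counts.counts):
        for term, n in doc_counts.items():
            col = index.get(term)
            if col is None:
                raise ValidationError(
                    f"term {term!r} in counts is missing from the lexicon"
                )
            out[row, col] = n
    return out


def weight_occurrence(
    counts: TermCounts, lexicon: PredictorLexicon
) -> DocTermMatrix:
    """Raw occurrence counts n_i,j (0 where the term is absent)."""
    return DocTermMatrix(
        doc_ids=counts.doc_ids,
        terms=tuple(lexicon.terms),
        values=_expand(counts, lexicon),
        weighting=OCCURRENCE,
    )


def weight_binary(counts: TermCounts, lexicon: PredictorLexicon) -> DocTermMatrix:
    """Presence/absence indicator per document and term."""
    return DocTermMatrix(
        doc_ids=counts.doc_ids,
        terms=tuple(lexicon.terms),
        values=(_expand(counts, lexicon) > 0).astype(float),
        weighting=BINARY,
    )


def weight_tfidf(
    counts: TermCounts,
    lexicon: PredictorLexicon,
    log_base: float = 10.0,
) -> DocTermMatrix:
    """TF-IDF weights, fitting the IDF table on these documents.

    A document whose token total is zero gets an all-zero row. Document
    frequencies come from the lexicon (fitted on the same corpus); every
    lexicon term must occur somewhere (n_i >= 1), which the lexicon's own
    invariant guarantees.
    """
    occ = _expand(counts, lexicon)
    totals = np.asarray(counts.totals, dtype=float)
    n_docs = len(counts)
    safe_totals = np.where(totals > 0, totals, 1.0)
    tf = occ / safe_totals[:, None]
    df = np.array([lexicon.document_frequencies[t] for t in lexicon.terms], dtype=float)
    idf = np.log(n_docs / df) / math.log(log_base)
    idf = np.maximum(idf, 0.0)  # guard: df can exceed the fitting count only by misuse
    return DocTermMatrix(
        doc_ids=counts.doc_ids,
        terms=tuple(lexicon.terms),
        values=tf * idf[None, :],
        weighting=TFIDF,
        idf_table=idf,
        n_fit=n_docs,
        log_base=log_base,
    )


def transform_new(fitted: DocTermMatrix, counts: TermCounts) -> DocTermMatrix:
    """Weight unseen documents in a fitted matrix's feature space.

    The fitted term order is preserved; terms the fitted lexicon does not
    know are ignored; for TF-IDF the *stored* IDF table is applied, never
    refitted.
    """
    index = {t: i for i, t in enumerate(fitted.terms)}
    occ = np.zeros((len(counts), len(fitted.terms)))
    for row, doc_counts in enumerate(counts.counts):
        for term, n in doc_counts.items():
            col = index.get(term)
            if col is not None:
                occ[row, col] = n
    if fitted.weighting == OCCURRENCE:
        values = occ
    elif fitted.weighting == BINARY:
        values = (occ > 0).astype(float)
    elif fitted.weighting == TFIDF:
        totals = np.asarray(counts.totals, dtype=float)
        safe_totals = np.where(totals > 0, totals, 1.0)
        tf = occ / safe_totals[:, None]
        values = tf * fitted.idf_table[None, :]
    else:  # pragma: no cover - DocTermMatrix already validates
        raise ValidationError(f"unknown weighting {fitted.weighting!r}")
    return DocTermMatrix(
        doc_ids=counts.doc_ids,
        terms=fitted.terms,
        values=values,
        weighting=fitted.weighting,
        idf_table=fitted.idf_table,
        n_fit=fitted.n_fit,
        log_base=fitted.log_base,
    )


def save_matrix(matrix: DocTermMatrix, prefix: str | Path) -> None:
    """Write MatrixMarket values plus sidecar term/doc lists and a header."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), scipy.sparse.coo_matrix(matrix.values))
    prefix.with_suffix(".terms.txt").write_text(
        "\n".join(matrix.terms) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(".docs.txt").write_text(
        "\n".join(matrix.doc_ids) + "\n", encoding="utf-8"
    )
    header = {
        "weighting": matrix.weighting,
        "n_fit": matrix.n_fit,
        "log_base": matrix.log_base,
        "idf_table": None if matrix.idf_table is None else matrix.idf_table.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(header), encoding="utf-8")


def load_matrix(prefix: str | Path) -> DocTermMatrix:
    prefix = Path(prefix)
    values = np.asarray(scipy.io.mmread(str(prefix.with_suffix(".mtx"))).todense())
    terms = tuple(prefix.with_suffix(".terms.txt").read_text(encoding="utf-8").split())
    doc_ids = tuple(prefix.with_suffix(".docs.txt").read_text(encoding="utf-8").split())
    header = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
    idf = header["idf_table"]
    return DocTermMatrix(
        doc_ids=doc_ids,
        terms=terms,
        values=values,
        weighting=header["weighting"],
        idf_table=None if idf is None else np.asarray(idf, dtype=float),
        n_fit=header["n_fit"],
        log_base=header["log_base"],
    )
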