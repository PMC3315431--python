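"""Reading, writing and splitting abstract corpora.

Records carry a PubMed-style identifier, a title and an abstract; only the
concatenated title + abstract text is ever mined. Corpora arrive either as
MEDLINE tagged text (PMID-/TI-/AB- fields) or as plain CSV
(doc_id,title,abstract[,label]); labels live in a separate two-column file
mapping identifiers to 'useful' / 'non-useful'.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import Medline

USEFUL = "useful"
NON_USEFUL = "non_useful"
UNLABELED = "unlabeled"
LABELS = (USEFUL, NON_USEFUL, UNLABELED)

_LABEL_ALIASES = {
    "useful": USEFUL,
    "non_useful": NON_USEFUL,
    "non-useful": NON_USEFUL,
    "nonuseful": NON_USEFUL,
    "unlabeled": UNLABELED,
    "unlabelled": UNLABELED,
}


class ValidationError(ValueError):
    """Raised when an input file or argument violates a documented contract."""


@dataclass(frozen=True)
class Document:
    """One abstract record. ``text`` is the string that gets mined."""

    doc_id: str
    title: str
    abstract: str = ""
    label: str = UNLABELED
    drug_class: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"label must be one of {LABELS}, got {self.label!r}"
            )

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


@dataclass
class Corpus:
    """An ordered collection of documents with unique identifiers."""

    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    def labels(self) -> list[str]:
        return [d.label for d in self.documents]

    def subset(self, doc_ids: Iterable[str], provenance: str = "") -> "Corpus":
        wanted = set(doc_ids)
        return Corpus(
            [d for d in self.documents if d.doc_id in wanted],
            provenance or self.provenance,
        )

    def with_labels(self, labels: Mapping[str, str]) -> "Corpus":
        """Return a copy with labels applied where the mapping covers a doc."""
        docs = [
            replace(d, label=labels[d.doc_id]) if d.doc_id in labels else d
            for d in self.documents
        ]
        return Corpus(docs, self.provenance)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.documents:
            counts[d.label] = counts.get(d.label, 0) + 1
        return counts


@dataclass(frozen=True)
class SplitSpec:
    """Stratified-split request: fractions per part, stratified on label."""

    fractions: Sequence[float]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValidationError("fractions must be non-empty")
        for f in self.fractions:
            if not (0.0 < f <= 1.0):
                raise ValidationError(f"fraction {f} outside (0, 1]")
        if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"fractions sum to {sum(self.fractions)}, expected 1"
            )


def read_medline(path: str | Path) -> Corpus:
    """Parse a MEDLINE tagged-text export into a Corpus.

    One Document per record; records lacking AB get an empty abstract.
    Continuation lines are joined single-spaced (Biopython's Medline parser).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        records = list(Medline.parse(handle))
    docs = []
    for rec in records:
        pmid = rec.get("PMID")
        if pmid is None:
            continue  # Medline.parse can emit an empty trailing record
        docs.append(
            Document(
                doc_id=pmid,
                title=rec.get("TI", ""),
                abstract=rec.get("AB", ""),
            )
        )
    try:
        return Corpus(docs, provenance=str(path))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_medline(corpus: Corpus, path: str | Path) -> None:
    """Write tagged MEDLINE text that round-trips through read_medline.

    Fields are written on single (unwrapped) lines, which the tagged format
    permits; titles/abstracts are whitespace-normalized on write because the
    dialect cannot represent internal newlines or runs of spaces.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as out:
        for doc in corpus:
            out.write(f"PMID- {doc.doc_id}\n")
            out.write(f"TI  - {' '.join(doc.title.split())}\n")
            if doc.abstract:
                out.write(f"AB  - {' '.join(doc.abstract.split())}\n")
            out.write("\n")


def read_csv_corpus(path: str | Path) -> Corpus:
    """Read a plain CSV corpus: doc_id,title,abstract[,label] with header."""
    path = Path(path)
    docs = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        required = {"doc_id", "title", "abstract"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"{path}: CSV header must contain {sorted(required)}"
            )
        for row in reader:
            label = _normalize_label(row.get("label") or UNLABELED, path, reader.line_num)
            docs.append(
                Document(
                    doc_id=row["doc_id"],
                    title=row["title"],
                    abstract=row["abstract"],
                    label=label,
                    drug_class=row.get("drug_class") or None,
                )
            )
    try:
        return Corpus(docs, provenance=str(path))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_csv_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["doc_id", "title", "abstract", "label", "drug_class"])
        for d in corpus:
            writer.writerow([d.doc_id, d.title, d.abstract, d.label, d.drug_class or ""])


def _normalize_label(token: str, path, line_num) -> str:
    norm = _LABEL_ALIASES.get(token.strip().lower())
    if norm is None:
        raise ValidationError(
            f"{path}: unknown label {token!r} at line {line_num}"
        )
    return norm


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (doc_id<TAB>label) file into a mapping.

    Label tokens are normalized case-insensitively to useful / non_useful.
    A doc_id repeated with conflicting labels is a validation error.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line_num, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}: expected 'doc_id<TAB>label' at line {line_num}"
                )
            doc_id, token = parts[0].strip(), parts[1]
            label = _normalize_label(token, path, line_num)
            if doc_id in labels and labels[doc_id] != label:
                raise ValidationError(
                    f"{path}: conflicting labels for {doc_id!r} at line {line_num}"
                )
            labels[doc_id] = label
    return labels


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion n items to parts so each count is within 1 of n*fraction."""
    exact = [n * f for f in fractions]
    counts = [int(math.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(
        range(len(fractions)),
        key=lambda i: (-(exact[i] - counts[i]), i),
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def stratified_split(corpus: Corpus, spec: SplitSpec) -> list[Corpus]:
    """Split a labeled corpus into parts preserving class proportions.

    Per class: shuffle that class's documents with the seeded generator,
    then cut into runs sized by largest-remainder apportionment. The same
    seed always yields the same partition; parts are disjoint and their
    union is the corpus (original document order restored within parts).
    """
    if any(d.label == UNLABELED for d in corpus):
        raise ValidationError("stratified_split requires every document labeled")
    by_class: dict[str, list[int]] = {}
    for idx, doc in enumerate(corpus):
        by_class.setdefault(doc.label, []).append(idx)
    n_parts = len(spec.fractions)
    for cls, members in by_class.items():
        if len(members) < n_parts:
            raise ValidationError(
                f"class {cls!r} has {len(members)} documents, fewer than "
                f"{n_parts} parts"
            )
    rng = np.random.default_rng(spec.seed)
    part_indices: list[list[int]] = [[] for _ in range(n_parts)]
    for cls in sorted(by_class):
        members = np.array(by_class[cls])
        rng.shuffle(members)
        counts = _largest_remainder(len(members), spec.fractions)
        start = 0
        for part, count in enumerate(counts):
            part_indices[part].extend(members[start : start + count].tolist())
            start += count
    parts = []
    for p, indices in enumerate(part_indices):
        docs = [corpus[i] for i in sorted(indices)]
        parts.append(Corpus(docs, provenance=f"{corpus.provenance} [part {p}]"))
    return parts


def write_ranking(
    corpus: Corpus, scores: Mapping[str, float], path: str | Path
) -> None:
    """Write a TSV of documents sorted by confidence, highest first.

    Columns: rank, doc_id, score, title. Ties broken by doc_id ascending.
    """
    for doc in corpus:
        score = scores.get(doc.doc_id)
        if score is None:
            raise ValidationError(f"no score for document {doc.doc_id!r}")
        if math.isnan(score):
            raise ValidationError(f"NaN score for document {doc.doc_id!r}")
    ordered = sorted(corpus, key=lambda d: (-scores[d.doc_id], d.doc_id))
    with open(path, "w", encoding="utf-8") as out:
        out.write("rank\tdoc_id\tscore\ttitle\n")
        for rank, doc in enumerate(ordered, start=1):
            out.write(f"{rank}\t{doc.doc_id}\t{scores[doc.doc_id]:.10g}\t{doc.title}\n")
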