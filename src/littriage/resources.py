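"""Lexical resources: stop words, synonym map, phrase list, general terms.

All four resources are plain text files:

* stopwords — one token per line
* synonyms — ``variant<TAB>canonical`` per line (canonical forms must not
  themselves be mapped further: the map is chain-free)
* phrases — one multiword term per line, space-separated tokens
* general terms — one term per line; terms usable across drug classes

Because the mining chain stems tokens before consulting any resource, the
resources are stemmed at load time (when stemming is enabled) so lookups
happen in the same space as the token stream. Entries whose variant and
canonical form collapse to the same stem are dropped as redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable

from .corpus_io import ValidationError
from .stemming import stem


@dataclass(frozen=True)
class ResourceSet:
    stopwords: frozenset[str] = frozenset()
    synonyms: dict[str, str] = field(default_factory=dict)
    phrases: tuple[tuple[str, ...], ...] = ()
    general_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for variant, canonical in self.synonyms.items():
            target = self.synonyms.get(canonical)
            if target is not None and target != canonical:
                raise ValidationError(
                    f"synonym chain: {variant!r} -> {canonical!r} -> {target!r}"
                )
        for phrase in self.phrases:
            if len(phrase) < 2:
                raise ValidationError(f"phrase {phrase!r} has fewer than 2 tokens")
            for token in phrase:
                if token in self.stopwords:
                    raise ValidationError(
                        f"stopword {token!r} appears in phrase {phrase!r}"
                    )


def _read_lines(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as handle:
        return [
            line.strip().lower()
            for line in handle
            if line.strip() and not line.startswith("#")
        ]


def _maybe_stem(token: str, do_stem: bool) -> str:
    if not do_stem:
        return token
    if "_" in token:  # joined multiword term: stem component-wise
        return "_".join(stem(part) for part in token.split("_"))
    return stem(token)


def load_resources(
    stopwords_path: str | Path | None = None,
    synonyms_path: str | Path | None = None,
    phrases_path: str | Path | None = None,
    general_terms_path: str | Path | None = None,
    use_stemming: bool = True,
) -> ResourceSet:
    """Load a ResourceSet from files, defaulting to the shipped lists.

    Pass an explicit path to override a shipped list (e.g. a full
    general-predictor list); stemming of entries tracks ``use_stemming``.
    """
    data = importlib_resources.files("littriage") / "data"

    def default(name: str) -> Path:
        return Path(str(data / name))

    stopwords = frozenset(
        _maybe_stem(t, use_stemming)
        for t in _read_lines(stopwords_path or default("stopwords.txt"))
    )

    synonyms: dict[str, str] = {}
    for line_num, line in enumerate(
        _read_lines(synonyms_path or default("synonyms.tsv")), start=1
    ):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"synonyms line {line_num}: expected 'variant<TAB>canonical'"
            )
        variant = _maybe_stem(parts[0].strip(), use_stemming)
        canonical = _maybe_stem(parts[1].strip(), use_stemming)
        if variant == canonical:
            continue
        if variant in synonyms and synonyms[variant] != canonical:
            raise ValidationError(
                f"synonyms line {line_num}: {variant!r} mapped to both "
                f"{synonyms[variant]!r} and {canonical!r}"
            )
        synonyms[variant] = canonical

    phrases = tuple(
        tuple(_maybe_stem(tok, use_stemming) for tok in line.split())
        for line in _read_lines(phrases_path or default("phrases.txt"))
    )

    general_terms = frozenset(
        _maybe_stem(t.replace(" ", "_"), use_stemming)
        for t in _read_lines(general_terms_path or default("general_terms.txt"))
    )

    return ResourceSet(
        stopwords=stopwords,
        synonyms=synonyms,
        phrases=phrases,
        general_terms=general_terms,
    )


def resource_set(
    stopwords: Iterable[str] = (),
    synonyms: dict[str, str] | None = None,
    phrases: Iterable[Iterable[str]] = (),
    general_terms: Iterable[str] = (),
    use_stemming: bool = True,
) -> ResourceSet:
    """Build a ResourceSet from in-memory collections (stemmed to match)."""
    return ResourceSet(
        stopwords=frozenset(_maybe_stem(t, use_stemming) for t in stopwords),
        synonyms={
            _maybe_stem(k, use_stemming): _maybe_stem(v, use_stemming)
            for k, v in (synonyms or {}).items()
            if _maybe_stem(k, use_stemming) != _maybe_stem(v, use_stemming)
        },
        phrases=tuple(
            tuple(_maybe_stem(tok, use_stemming) for tok in phrase)
            for phrase in phrases
        ),
        general_terms=frozenset(
            _maybe_stem(t, use_stemming) for t in general_terms
        ),
    )
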