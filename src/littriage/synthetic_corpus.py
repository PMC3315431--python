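"""Synthetic labeled abstract corpora with planted class signal.

Emulates the statistical structure the triage systems assume: a minority
'useful' class (default prevalence 17.5%), a vocabulary mixing general
(drug-class-agnostic) signal terms, class-specific signal terms and noise
terms, and documents that are bags of tokens drawn from a per-class
multinomial. Useful documents oversample the signal vocabulary by a
multiplicative enrichment factor; non-useful documents draw uniformly.

Each drug class *activates* a random subset of the shared general
vocabulary (default 70%): useful articles of different classes express
overlapping but not identical general signals, which is what makes a
general system transfer to unseen classes imperfectly.

Generated terms are lowercase consonant-suffixed pseudo-words chosen to be
fixed points of the stemmer and disjoint from the stop-word list, so the
mining chain passes them through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import NON_USEFUL, USEFUL, Corpus, Document, ValidationError
from .resources import ResourceSet

_SUFFIX_ALPHABET = "bcdfgkmnpqrtvwxz"  # no vowels, no s/l/y: stemmer-inert


@dataclass(frozen=True)
class GeneratorConfig:
    n_documents: int = 1000
    prevalence: float = 0.175
    n_general: int = 60
    n_specific: int = 40
    n_noise: int = 400
    enrichment: float = 5.0
    doc_length_mean: float = 120.0
    doc_length_dispersion: float = 20.0  # negative-binomial shape r
    n_drug_classes: int = 1
    general_active_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must be in (0, 1)")
        if self.enrichment < 1.0:
            raise ValidationError("enrichment must be >= 1")
        if min(self.n_general, self.n_specific, self.n_noise) < 1:
            raise ValidationError("vocabulary sizes must be >= 1")
        if self.n_documents < 1:
            raise ValidationError("n_documents must be >= 1")
        if self.n_drug_classes < 1:
            raise ValidationError("n_drug_classes must be >= 1")
        if not (0.0 < self.general_active_fraction <= 1.0):
            raise ValidationError("general_active_fraction must be in (0, 1]")
        if self.doc_length_mean <= 0 or self.doc_length_dispersion <= 0:
            raise ValidationError("document length parameters must be > 0")


def _suffix(i: int, width: int = 3) -> str:
    base = len(_SUFFIX_ALPHABET)
    chars = []
    for _ in range(width):
        chars.append(_SUFFIX_ALPHABET[i % base])
        i //= base
    return "".join(reversed(chars))


def vocabulary(config: GeneratorConfig) -> dict:
    """The generator's term inventory (ground truth for recovery tests)."""
    general = [f"gpred{_suffix(i)}" for i in range(config.n_general)]
    specific = {
        c: [f"spred{_SUFFIX_ALPHABET[c]}{_suffix(i)}" for i in range(config.n_specific)]
        for c in range(config.n_drug_classes)
    }
    noise = [f"nterm{_suffix(i)}" for i in range(config.n_noise)]
    return {"general": general, "specific": specific, "noise": noise}


def _class_rng(
    config: GeneratorConfig, drug_class: int, stream: int = 0
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(drug_class, stream))
    )


def active_general_terms(config: GeneratorConfig, drug_class: int = 0) -> list[str]:
    """The subset of general terms this drug class's useful articles enrich."""
    general = vocabulary(config)["general"]
    n_active = max(1, round(config.general_active_fraction * len(general)))
    rng = _class_rng(config, drug_class)
    idx = rng.choice(len(general), size=n_active, replace=False)
    return [general[i] for i in sorted(idx)]


def generate_corpus(
    config: GeneratorConfig, drug_class: int = 0
) -> tuple[Corpus, ResourceSet]:
    """One labeled corpus for one drug class, plus the true resource set.

    The returned ResourceSet carries the full general-term vocabulary as
    its general list (what a curated general-predictor list would be) and
    empty stop-word/synonym/phrase lists. Deterministic per (seed, class).
    """
    if drug_class >= config.n_drug_classes:
        raise ValidationError(
            f"drug_class {drug_class} out of range for "
            f"{config.n_drug_classes} classes"
        )
    vocab = vocabulary(config)
    words = np.array(
        vocab["general"] + vocab["specific"][drug_class] + vocab["noise"]
    )
    n_words = len(words)

    signal = np.zeros(n_words, dtype=bool)
    active = set(active_general_terms(config, drug_class))
    for i, w in enumerate(vocab["general"]):
        if w in active:
            signal[i] = True
    signal[config.n_general : config.n_general + config.n_specific] = True

    weights_useful = np.where(signal, config.enrichment, 1.0)
    p_useful = weights_useful / weights_useful.sum()
    p_plain = np.full(n_words, 1.0 / n_words)

    rng = _class_rng(config, drug_class, stream=1)
    labels = rng.random(config.n_documents) < config.prevalence
    r = config.doc_length_dispersion
    lengths = rng.negative_binomial(
        r, r / (r + config.doc_length_mean), size=config.n_documents
    )
    lengths = np.maximum(lengths, 20)

    docs = []
    base_id = (drug_class + 1) * 1_000_000
    for i in range(config.n_documents):
        p = p_useful if labels[i] else p_plain
        tokens = rng.choice(words, size=int(lengths[i]), p=p)
        docs.append(
            Document(
                doc_id=str(base_id + i),
                title=" ".join(tokens[:8]),
                abstract=" ".join(tokens[8:]),
                label=USEFUL if labels[i] else NON_USEFUL,
                drug_class=f"class{drug_class}",
            )
        )
    corpus = Corpus(
        docs,
        provenance=(
            f"synthetic drug class {drug_class} "
            f"(seed {config.seed}, n {config.n_documents})"
        ),
    )
    resources = ResourceSet(general_terms=frozenset(vocab["general"]))
    return corpus, resources


def generate_multiclass(
    config: GeneratorConfig,
) -> tuple[list[Corpus], ResourceSet]:
    """One corpus per drug class sharing the general vocabulary.

    Class-specific vocabularies are disjoint across classes. Class 0 plays
    the training-class role; the rest form the generalizability material.
    """
    if config.n_drug_classes < 2:
        raise ValidationError("generate_multiclass needs n_drug_classes >= 2")
    corpora = []
    resources = None
    for c in range(config.n_drug_classes):
        corpus, resources = generate_corpus(config, drug_class=c)
        corpora.append(corpus)
    return corpora, resources


def with_permuted_labels(corpus: Corpus, seed: int) -> Corpus:
    """Same documents, labels randomly reassigned: the no-signal null."""
    rng = np.random.default_rng(seed)
    labels = [d.label for d in corpus]
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    return Corpus(
        [replace(d, label=lab) for d, lab in zip(corpus, permuted)],
        provenance=f"{corpus.provenance} [permuted labels]",
    )
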