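"""The two deliverables: general and specific automated triage systems.

A *general* system is trained once on a labeled corpus using only the
general (drug-class-agnostic) predictors, so it can rank articles of any
drug class. A *specific* system is bootstrapped per drug class: a small
number of documents (~20) is selected — by Kennard-Stone dissimilarity or
by the general system's confidence extremes — labeled by an evaluator
(modeled here as an oracle mapping), and a fresh system using *all*
predictors of those documents is trained on them.

Both systems rank unlabeled articles by the classifier's confidence of
'useful', highest first, which is the order an evaluator reviews them in.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import NON_USEFUL, USEFUL, Corpus, ValidationError
from .evaluation import auc
from .features import (
    BINARY,
    OCCURRENCE,
    TFIDF,
    DocTermMatrix,
    transform_new,
    weight_binary,
    weight_occurrence,
    weight_tfidf,
)
from .models import ModelConfig, Prediction, TrainedModel, score, train
from .resources import ResourceSet
from .sampling import confidence_extremes, kennard_stone
from .text_processing import (
    PredictorLexicon,
    TermCounts,
    count_corpus,
    extract_predictors,
    restrict_general,
)

logger = logging.getLogger(__name__)

GENERAL_KIND = "general"
SPECIFIC_KIND = "specific"

KENNARD_STONE = "kennard_stone"
CONFIDENCE_EXTREMES = "confidence_extremes"


def featurize(
    counts: TermCounts, lexicon: PredictorLexicon, weighting: str = TFIDF
) -> DocTermMatrix:
    if weighting == TFIDF:
        return weight_tfidf(counts, lexicon)
    if weighting == OCCURRENCE:
        return weight_occurrence(counts, lexicon)
    if weighting == BINARY:
        return weight_binary(counts, lexicon)
    raise ValidationError(f"unknown weighting {weighting!r}")


@dataclass(frozen=True)
class AutomatedSystem:
    """A fitted triage system: lexicon, fitted features and classifier."""

    kind: str
    resources: ResourceSet = field(repr=False)
    lexicon: PredictorLexicon = field(repr=False)
    fitted_matrix: DocTermMatrix = field(repr=False)
    model: TrainedModel = field(repr=False)
    use_stemming: bool = True

    def __post_init__(self) -> None:
        if self.kind not in (GENERAL_KIND, SPECIFIC_KIND):
            raise ValidationError(f"unknown system kind {self.kind!r}")
        if self.kind == GENERAL_KIND:
            bad = [e.term for e in self.lexicon.entries if e.category != "general"]
            if bad:
                raise ValidationError(
                    f"general system lexicon contains specific terms: {bad[:5]}"
                )
        if self.model.terms != tuple(self.lexicon.terms):
            raise ValidationError("model term order differs from lexicon")

    @property
    def weighting(self) -> str:
        return self.fitted_matrix.weighting


def build_general_system(
    training_corpus: Corpus,
    resources: ResourceSet,
    model_config: ModelConfig | None = None,
    weighting: str = TFIDF,
    min_document_frequency: int = 2,
    use_stemming: bool = True,
) -> AutomatedSystem:
    """Train a general system: general predictors only, TF-IDF + SVM default."""
    model_config = model_config or ModelConfig()
    lexicon, counts = extract_predictors(
        training_corpus, resources, min_document_frequency, use_stemming
    )
    general_lexicon = restrict_general(lexicon)
    counts = counts.restrict(general_lexicon.terms)
    matrix = featurize(counts, general_lexicon, weighting)
    model = train(matrix, training_corpus.labels(), model_config)
    return AutomatedSystem(
        kind=GENERAL_KIND,
        resources=resources,
        lexicon=general_lexicon,
        fitted_matrix=matrix,
        model=model,
        use_stemming=use_stemming,
    )


def build_specific_system(
    training_corpus: Corpus,
    resources: ResourceSet,
    model_config: ModelConfig | None = None,
    weighting: str = TFIDF,
    min_document_frequency: int = 2,
    use_stemming: bool = True,
) -> AutomatedSystem:
    """Train a specific system on a (small) labeled corpus, all predictors."""
    model_config = model_config or ModelConfig()
    lexicon, counts = extract_predictors(
        training_corpus, resources, min_document_frequency, use_stemming
    )
    matrix = featurize(counts, lexicon, weighting)
    model = train(matrix, training_corpus.labels(), model_config)
    return AutomatedSystem(
        kind=SPECIFIC_KIND,
        resources=resources,
        lexicon=lexicon,
        fitted_matrix=matrix,
        model=model,
        use_stemming=use_stemming,
    )


def score_corpus(system: AutomatedSystem, corpus: Corpus) -> list[Prediction]:
    """Predictions in corpus order (no ranking applied)."""
    counts = count_corpus(corpus, system.resources, system.use_stemming)
    matrix = transform_new(system.fitted_matrix, counts)
    if matrix.shape[0] and not matrix.values.any():
        logger.warning(
            "every document reduced to a zero vector under the fitted "
            "lexicon; confidences are uninformative and input order is kept"
        )
        return score(system.model, matrix)
    return score(system.model, matrix)


def rank_articles(system: AutomatedSystem, corpus: Corpus) -> list[Prediction]:
    """Score a corpus and return predictions by confidence, highest first.

    Ties break by doc_id ascending; if every document maps to a zero
    vector the input order is preserved (with a warning from scoring).
    """
    if len(corpus) == 0:
        raise ValidationError("cannot rank an empty corpus")
    predictions = score_corpus(system, corpus)
    if len({p.confidence for p in predictions}) == 1:
        return predictions
    return sorted(predictions, key=lambda p: (-p.confidence, p.doc_id))


def system_auc(system: AutomatedSystem, labeled_corpus: Corpus) -> float:
    """AUC of the system's confidences against the corpus labels."""
    predictions = score_corpus(system, labeled_corpus)
    return auc([p.confidence for p in predictions], labeled_corpus.labels())


def bootstrap_specific(
    system: AutomatedSystem,
    corpus: Corpus,
    oracle_labels: Mapping[str, str],
    n_label: int = 20,
    selection: str = CONFIDENCE_EXTREMES,
    model_config: ModelConfig | None = None,
    weighting: str = TFIDF,
    min_document_frequency: int = 2,
) -> AutomatedSystem:
    """One bootstrap round: select ~20 documents, label them, train specific.

    ``oracle_labels`` stands in for the human evaluator and must cover the
    selected documents. The specific system extracts its own lexicon (all
    predictors, general and specific) and IDF from the selected documents
    only. A single-class selection is an error — switch the selection
    method (confidence extremes favours getting both classes).
    """
    if n_label < 2:
        raise ValidationError("n_label must be >= 2")
    if n_label > len(corpus):
        raise ValidationError(
            f"n_label {n_label} exceeds corpus size {len(corpus)}"
        )
    if selection == KENNARD_STONE:
        lexicon, counts = extract_predictors(
            corpus, system.resources, min_document_frequency, system.use_stemming
        )
        matrix = featurize(counts, lexicon, weighting)
        result = kennard_stone(matrix, n_label)
        selected_ids = [corpus[i].doc_id for i in result.indices]
    elif selection == CONFIDENCE_EXTREMES:
        predictions = rank_articles(system, corpus)
        selected_ids = confidence_extremes(predictions, n_label)
    else:
        raise ValidationError(f"unknown selection method {selection!r}")

    missing = [d for d in selected_ids if d not in oracle_labels]
    if missing:
        raise ValidationError(f"oracle labels missing for {missing[:5]}")
    labeled = corpus.subset(selected_ids).with_labels(oracle_labels)
    classes = {d.label for d in labeled}
    if classes == {USEFUL} or classes == {NON_USEFUL}:
        raise ValidationError(
            "the selected documents all carry one label; a specific system "
            "cannot be trained from a single-class selection — try the "
            "confidence_extremes selection method or a larger n_label"
        )
    return build_specific_system(
        labeled,
        system.resources,
        model_config,
        weighting,
        min_document_frequency,
        system.use_stemming,
    )


def training_size_experiment(
    dataset_a: Corpus,
    validation: Corpus,
    sizes: Sequence[int],
    resources: ResourceSet,
    model_config: ModelConfig | None = None,
    weighting: str = TFIDF,
    min_document_frequency: int = 2,
    use_stemming: bool = True,
) -> pd.DataFrame:
    """AUC as a function of Kennard-Stone training-set size.

    All predictors of dataset A are extracted once; for each requested
    size the first ``size`` Kennard-Stone selections train a classifier
    (remaining dataset-A documents form the testing set), which is then
    scored on the validation corpus. Sizes must be ascending and leave a
    non-empty testing set.

    A selection containing a single class cannot train a discriminative
    classifier; it degenerates to a constant-confidence ranker whose AUC
    is exactly 0.5 under the tie-credit definition, and the row reports
    that with trained = False.

    Returns a DataFrame with columns size, n_useful, n_non_useful, ratio,
    trained and auc.
    """
    model_config = model_config or ModelConfig()
    if list(sizes) != sorted(sizes):
        raise ValidationError("sizes must be ascending")
    for size in sizes:
        if size >= len(dataset_a):
            raise ValidationError(
                f"size {size} leaves no testing documents in dataset A "
                f"(n = {len(dataset_a)})"
            )
    lexicon, counts = extract_predictors(
        dataset_a, resources, min_document_frequency, use_stemming
    )
    matrix = featurize(counts, lexicon, weighting)
    val_counts = count_corpus(validation, resources, use_stemming)
    val_matrix = transform_new(matrix, val_counts)
    labels = dataset_a.labels()
    selection = kennard_stone(matrix, max(sizes))
    rows = []
    for size in sizes:
        chosen = list(selection.indices[:size])
        chosen_labels = [labels[i] for i in chosen]
        n_useful = chosen_labels.count(USEFUL)
        n_non = chosen_labels.count(NON_USEFUL)
        ratio = f"1: {n_non / n_useful:g}" if n_useful else f"0: {n_non}"
        trained = n_useful > 0 and n_non > 0
        if not trained:
            # constant-confidence ranker: every pair is a tie, AUC = 1/2
            value = 0.5
        else:
            sub = DocTermMatrix(
                doc_ids=tuple(matrix.doc_ids[i] for i in chosen),
                terms=matrix.terms,
                values=matrix.values[chosen],
                weighting=matrix.weighting,
                idf_table=matrix.idf_table,
                n_fit=matrix.n_fit,
                log_base=matrix.log_base,
            )
            model = train(sub, chosen_labels, model_config)
            predictions = score(model, val_matrix)
            value = auc([p.confidence for p in predictions], validation.labels())
        rows.append(
            {
                "size": size,
                "n_useful": n_useful,
                "n_non_useful": n_non,
                "ratio": ratio,
                "trained": trained,
                "auc": value,
            }
        )
    return pd.DataFrame(rows)


_PERSIST_VERSION = 1


def save_system(system: AutomatedSystem, path: str | Path) -> None:
    with open(path, "wb") as out:
        pickle.dump({"version": _PERSIST_VERSION, "system": system}, out)


def load_system(path: str | Path) -> AutomatedSystem:
    with open(path, "rb") as handle:
        payload = pickle.load(handle)
    if payload.get("version") != _PERSIST_VERSION:
        raise ValidationError(
            f"unsupported system archive version: {payload.get('version')}"
        )
    return payload["system"]
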