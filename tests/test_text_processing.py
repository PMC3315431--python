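"""The mining chain: tokens, stop words, synonyms, phrases, predictors."""

import pytest

from littriage.corpus_io import Corpus, Document, ValidationError
from littriage.resources import ResourceSet, load_resources, resource_set
from littriage.stemming import stem
from littriage.text_processing import (
    GENERAL,
    SPECIFIC,
    count_corpus,
    detect_phrases,
    extract_predictors,
    merge_synonyms,
    process_text,
    remove_stopwords,
    restrict_general,
    tokenize,
)


class TestTokenize:
    def test_punctuation_lowercasing_and_hyphen_split(self):
        assert tokenize("TNF-α blockers, e.g. infliximab.") == [
            "tnf", "α", "blockers", "e", "g", "infliximab",
        ]

    def test_empty_text(self):
        assert tokenize("") == []

    def test_three_sentence_abstract_matches_hand_tokenization(self):
        text = (
            "Infliximab was well-tolerated. Two patients developed "
            "opportunistic infections (3.5%). No deaths occurred."
        )
        # hand tokenization: lowercase, punctuation stripped, hyphens
        # split, pure numbers dropped
        assert tokenize(text) == [
            "infliximab", "was", "well", "tolerated", "two", "patients",
            "developed", "opportunistic", "infections", "no",
            "deaths", "occurred",
        ]

    def test_pure_digit_tokens_dropped(self):
        assert tokenize("10 mg dose") == ["mg", "dose"]


class TestStopwordsAndSynonyms:
    def test_prepositions_removed_in_order(self):
        tokens = ["while", "tnf", "to", "works", "on"]
        assert remove_stopwords(tokens, {"while", "to", "on"}) == ["tnf", "works"]

    def test_empty_stoplist_is_identity(self):
        tokens = ["a", "b"]
        assert remove_stopwords(tokens, set()) == tokens

    def test_all_stopwords_gives_empty(self):
        assert remove_stopwords(["to", "on"], {"to", "on"}) == []

    def test_british_variant_mapped(self):
        assert merge_synonyms(["tumour"], {"tumour": "tumor"}) == ["tumor"]

    def test_empty_map_is_identity(self):
        assert merge_synonyms(["x", "y"], {}) == ["x", "y"]

    def test_matches_tokenwise_lookup_oracle(self):
        tokens = [f"t{i}" for i in range(20)]
        mapping = {f"t{i}": f"c{i}" for i in range(0, 20, 4)}
        expected = [mapping.get(t, t) for t in tokens]
        assert merge_synonyms(tokens, mapping) == expected

    def test_chained_map_rejected(self):
        with pytest.raises(ValidationError, match="chain"):
            merge_synonyms(["a"], {"a": "b", "b": "c"})

    def test_chained_map_rejected_at_resource_construction(self):
        with pytest.raises(ValidationError, match="chain"):
            ResourceSet(synonyms={"a": "b", "b": "c"})


class TestDetectPhrases:
    def test_paper_style_phrase_joined(self):
        tokens = ["tumor", "necrosis", "factor", "alpha"]
        out = detect_phrases(tokens, [("tumor", "necrosis", "factor")])
        assert out == ["tumor_necrosis_factor", "alpha"]

    def test_no_match_is_identity(self):
        tokens = ["alpha", "beta"]
        assert detect_phrases(tokens, [("gamma", "delta")]) == tokens

    def test_leftmost_wins_on_overlap(self):
        out = detect_phrases(
            ["a", "b", "c", "d"], [("a", "b", "c"), ("b", "c", "d")]
        )
        assert out == ["a_b_c", "d"]

    def test_longest_match_at_position(self):
        out = detect_phrases(
            ["a", "b", "c"], [("a", "b"), ("a", "b", "c")]
        )
        assert out == ["a_b_c"]


def _two_doc_corpus() -> Corpus:
    return Corpus(
        [
            Document("1", "Tumour necrosis factor safety",
                     "Adverse events while treating tumours."),
            Document("2", "Safety of infliximab",
                     "No adverse events on treatment."),
        ]
    )


def _toy_resources() -> ResourceSet:
    return resource_set(
        stopwords=["while", "to", "on", "of", "no"],
        synonyms={"tumour": "tumor", "tumours": "tumors"},
        phrases=[["tumor", "necrosis", "factor"]],
        general_terms=["safety", "adverse"],
    )


class TestExtractPredictors:
    def test_hand_computed_lexicon_and_counts(self):
        # hand-run of the chain on both documents:
        # doc 1: tumour necrosis factor safety adverse events while
        #        treating tumours
        #   stem -> tumour necrosi factor safeti advers event while treat
        #           tumour  (stems: tumours -> tumour)
        #   stop -> (while removed)
        #   syn  -> tumor necrosi factor safeti advers event treat tumor
        #   phr  -> tumor_necrosis_factor(stemmed: tumor_necrosi_factor)
        #           safeti advers event treat tumor
        # doc 2: safety of infliximab no adverse events on treatment
        #   -> safeti infliximab advers event treatment->treatment stems
        #      to 'treatment'? 'treatment' -> 'treatment' (ment needs m>1)
        corpus = _two_doc_corpus()
        res = _toy_resources()
        lexicon, counts = extract_predictors(corpus, res, min_document_frequency=1)
        by_doc = {d: c for d, c in zip(counts.doc_ids, counts.counts)}
        phrase_term = "_".join([stem("tumor"), stem("necrosis"), stem("factor")])
        assert by_doc["1"] == {
            phrase_term: 1,
            stem("safety"): 1,
            stem("adverse"): 1,
            stem("events"): 1,
            stem("treating"): 1,
            stem("tumor"): 1,
        }
        assert by_doc["2"] == {
            stem("safety"): 1,
            stem("infliximab"): 1,
            stem("adverse"): 1,
            stem("events"): 1,
            stem("treatment"): 1,
        }
        # totals are the post-chain token counts before pruning
        assert counts.totals == (6, 5)
        df = lexicon.document_frequencies
        assert df[stem("safety")] == 2
        assert df[phrase_term] == 1
        cats = lexicon.categories
        assert cats[stem("safety")] == GENERAL
        assert cats[stem("adverse")] == GENERAL
        assert cats[stem("infliximab")] == SPECIFIC

    def test_min_df_above_corpus_size_rejected(self):
        with pytest.raises(ValidationError, match="frequency"):
            extract_predictors(
                _two_doc_corpus(), _toy_resources(), min_document_frequency=3
            )

    def test_singleton_term_pruned_at_min_df_2(self):
        lexicon, counts = extract_predictors(
            _two_doc_corpus(), _toy_resources(), min_document_frequency=2
        )
        assert stem("infliximab") not in lexicon.terms
        assert all(
            stem("infliximab") not in c for c in counts.counts
        )

    def test_counts_and_lexicon_terms_coincide(self):
        lexicon, counts = extract_predictors(
            _two_doc_corpus(), _toy_resources(), min_document_frequency=1
        )
        in_counts = set().union(*counts.counts)
        assert in_counts == set(lexicon.terms)

    def test_deterministic(self):
        a = extract_predictors(_two_doc_corpus(), _toy_resources(), 1)
        b = extract_predictors(_two_doc_corpus(), _toy_resources(), 1)
        assert a == b


class TestRestrictGeneral:
    def test_keeps_general_only(self):
        lexicon, _ = extract_predictors(
            _two_doc_corpus(), _toy_resources(), min_document_frequency=1
        )
        general = restrict_general(lexicon)
        assert set(general.categories.values()) == {GENERAL}
        assert set(general.terms) == {stem("safety"), stem("adverse")}
        # document frequencies unchanged
        for term in general.terms:
            assert (
                general.document_frequencies[term]
                == lexicon.document_frequencies[term]
            )

    def test_all_general_is_identity(self):
        lexicon, _ = extract_predictors(
            _two_doc_corpus(), _toy_resources(), min_document_frequency=1
        )
        general = restrict_general(lexicon)
        assert restrict_general(general) == general

    def test_intersection_oracle_on_synthetic_lexicon(self):
        res = load_resources()
        corpus = Corpus(
            [
                Document(str(i), f"word{i} adverse safety trial mortality",
                         "risk of death and toxicity in patients")
                for i in range(10)
            ]
        )
        lexicon, _ = extract_predictors(corpus, res, min_document_frequency=1)
        general = restrict_general(lexicon)
        oracle = set(lexicon.terms) & res.general_terms
        assert set(general.terms) == oracle


class TestChainProperties:
    def test_stopword_synonym_order_immaterial_for_disjoint_resources(self):
        # resources are disjoint: no synonym output is a stopword and no
        # stopword is a synonym key, so the two stages commute
        text = "Tumour necrosis factor events while on treatment"
        res = _toy_resources()
        tokens = [stem(t) for t in tokenize(text)]
        a = merge_synonyms(
            remove_stopwords(tokens, res.stopwords), res.synonyms
        )
        b = remove_stopwords(
            merge_synonyms(tokens, res.synonyms), res.stopwords
        )
        assert a == b

    def test_process_text_deterministic(self):
        res = load_resources()
        text = "Serious adverse events after tumour necrosis factor blockade."
        assert process_text(text, res) == process_text(text, res)

    def test_count_corpus_totals_cover_counts(self):
        res = load_resources()
        counts = count_corpus(_two_doc_corpus(), res)
        for c, total in zip(counts.counts, counts.totals):
            assert sum(c.values()) == total


class TestTokenizerProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.text(max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_tokens_are_lowercase_nondigit_alnum(self, text):
        for token in tokenize(text):
            assert token == token.lower()
            assert not token.isdigit()
            assert all(ch.isalnum() for ch in token)

    @given(
        st.lists(st.sampled_from(["tnf", "safety", "to", "on", "risk"]), max_size=30),
        st.sets(st.sampled_from(["to", "on", "of"])),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_stopword_removal_is_an_order_preserving_subsequence(
        self, tokens, stopwords
    ):
        out = remove_stopwords(tokens, stopwords)
        assert not set(out) & stopwords
        it = iter(tokens)
        assert all(any(t == u for u in it) for t in out)
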