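"""Text preparation, NER, event extraction and recall evaluation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from belflow.extraction import (
    BelClass,
    Dictionary,
    DictionaryError,
    EventType,
    Passage,
    Section,
    clean_text,
    evaluate_recall,
    extract_events,
    ner,
    segment_sentences,
    select_sections,
)
from belflow.fixtures import GeneratorConfig, generate_corpus

from conftest import EVIDENCE_SENTENCE


def run_extraction(corpus):
    """Pipeline NER+events over a gold corpus; returns keyed found sets."""
    found_mentions, found_events = [], []
    for p in select_sections(corpus.passages):
        segment_sentences(p)
        for si, (_, sentence) in enumerate(p.sentences):
            key = (p.pmid, p.section.value, si)
            mentions = ner(sentence, corpus.dictionaries)
            found_mentions.extend((key, m) for m in mentions)
            found_events.extend((key, e) for e in extract_events(sentence, mentions))
    return found_mentions, found_events


class TestCleanText:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("athero-\nsclerosis", "atherosclerosis"),           # de-hyphenation
            ("plaque\ndestabilization", "plaque destabilization"),  # line join
            ("CHEBI:‘20-HETE’", "CHEBI:'20-HETE'"),              # smart quotes
            ("eﬃcient ﬁbrous cap", "efficient fibrous cap"),      # ligatures
            ("range 3–5 weeks", "range 3-5 weeks"),               # en dash
            ("text\x00with\x07controls", "textwithcontrols"),
        ],
    )
    def test_normalization_cases(self, raw, expected):
        assert clean_text(raw) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(max_size=200))
    def test_idempotent_on_arbitrary_text(self, raw):
        once = clean_text(raw)
        assert clean_text(once) == once

    def test_idempotent(self):
        raws = [
            "athero-\nsclerosis of the ‘vulnerable’ plaque\nwith ﬁbrosis",
            "already clean text.",
            EVIDENCE_SENTENCE,
        ]
        for raw in raws:
            once = clean_text(raw)
            assert clean_text(once) == once


class TestSelectSections:
    def test_exclusion_rule(self):
        order = [
            Section.abstract,
            Section.introduction,
            Section.results,
            Section.discussion,
        ]
        passages = [Passage("1", s, f"text {s.value}") for s in order]
        kept = select_sections(passages)
        assert [p.section for p in kept] == [Section.abstract, Section.results]

    def test_all_excluded_warns(self):
        passages = [Passage("9", Section.discussion, "x")]
        with pytest.warns(UserWarning, match="article 9"):
            assert select_sections(passages) == []

    def test_matches_brute_force_filter(self, rng):
        sections = list(Section)
        passages = [
            Passage(str(a), rng.choice(sections), "t")
            for a in range(7)
            for _ in range(6)
        ]
        expected = [
            p
            for p in passages
            if p.section in (Section.abstract, Section.methods, Section.results)
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert select_sections(passages) == expected


class TestSegmentSentences:
    def test_two_simple_sentences(self):
        p = Passage("1", Section.results, "CYP4A11 was induced. MMP9 increased.")
        segment_sentences(p)
        assert [t for _, t in p.sentences] == [
            "CYP4A11 was induced.",
            "MMP9 increased.",
        ]

    def test_statistics_heavy_sentence_stays_whole(self):
        # decimals, ± and nested parentheses must not split the evidence
        p = Passage("21120482", Section.results, clean_text(EVIDENCE_SENTENCE))
        segment_sentences(p)
        assert len(p.sentences) == 1

    def test_abbreviations_do_not_split(self):
        p = Passage(
            "1",
            Section.results,
            "As shown by Smith et al. the lesions grew. See Fig. 2 for detail.",
        )
        segment_sentences(p)
        assert len(p.sentences) == 2

    def test_spans_cover_nonwhitespace_and_match_slices(self, clean_corpus):
        for passage in clean_corpus.passages[:6]:
            segment_sentences(passage)
            covered = set()
            for (s0, s1), sent in passage.sentences:
                assert passage.text[s0:s1] == sent
                assert not covered & set(range(s0, s1))  # disjoint, ordered
                covered.update(range(s0, s1))
            leftover = [
                c
                for i, c in enumerate(passage.text)
                if i not in covered and not c.isspace()
            ]
            assert leftover == []

    def test_planted_boundaries_recovered_exactly(self, clean_corpus):
        # generator knows its gold sentence spans by construction
        for passage in clean_corpus.passages:
            gold = list(passage.sentences)
            segment_sentences(passage)
            assert passage.sentences == gold


class TestNer:
    def test_worked_example_sentence(self, dictionaries):
        sentence = "CYP4A11 transfection significantly increased microvessel density"
        mentions = ner(sentence, dictionaries)
        assert [(m.namespace, m.id) for m in mentions] == [
            ("HGNC", "CYP4A11"),
            ("GOBP", "angiogenesis"),  # microvessel density normalizes here
        ]
        for m in mentions:
            assert sentence[m.char_span[0] : m.char_span[1]] == m.matched_text

    def test_no_hit_empty(self, dictionaries):
        assert ner("The samples were centrifuged briefly.", dictionaries) == []

    def test_longest_match_wins(self):
        d = Dictionary(
            "GOBP",
            BelClass.process,
            {
                "blood vessel development": {"blood vessel development"},
                "coagulation": {"blood coagulation"},
            },
        )
        mentions = ner("Impaired blood vessel development was seen.", [d])
        assert [m.id for m in mentions] == ["blood vessel development"]

    def test_short_tokens_match_case_sensitively(self):
        d = Dictionary("HGNC", BelClass.gene_protein, {"CAT": {"CAT"}})
        assert ner("The CAT gene was deleted.", [d])
        assert ner("The cat sat on the mat.", [d]) == []

    def test_long_names_match_case_insensitively(self, dictionaries):
        assert ner("Angiogenesis was assessed.", dictionaries)

    def test_collision_rejected_at_load(self):
        with pytest.raises(DictionaryError, match="maps to both"):
            Dictionary(
                "HGNC",
                BelClass.gene_protein,
                {"MMP9": {"gelatinase"}, "MMP2": {"gelatinase"}},
            )

    def test_token_boundary_anchoring(self, dictionaries):
        # CAT appears inside "CATALOG" but must not match mid-token
        assert all(
            m.matched_text != "CAT" for m in ner("The CATALOG listed it.", dictionaries)
        )

    def test_planted_corpus_mentions_equal_gold(self, clean_corpus):
        found, _ = run_extraction(clean_corpus)

        def keyset(pairs):
            return {(k, m.char_span, m.namespace, m.id) for k, m in pairs}

        assert keyset(found) == keyset(clean_corpus.gold_mentions)

    def test_determinism_and_priority_independence_of_file_order(self, dictionaries):
        sentence = "Notably, MMP9 significantly increased collagen degradation."
        a = ner(sentence, dictionaries)
        b = ner(sentence, dictionaries)
        assert a == b


class TestExtractEvents:
    def test_worked_example_event(self, dictionaries):
        sentence = "CYP4A11 transfection significantly increased microvessel density"
        mentions = ner(sentence, dictionaries)
        (event,) = extract_events(sentence, mentions)
        assert event.type is EventType.Positive_regulation
        assert event.cause.id == "CYP4A11"
        assert event.theme.id == "angiogenesis"

    def test_themeless_trigger_yields_nothing(self, dictionaries):
        sentence = "VEGFA increased"
        assert extract_events(sentence, ner(sentence, dictionaries)) == []

    def test_negation_dropped_by_default_kept_on_flag(self, dictionaries):
        sentence = "However, CD40LG did not increase chemotaxis in mice."
        mentions = ner(sentence, dictionaries)
        assert extract_events(sentence, mentions) == []
        kept = extract_events(sentence, mentions, keep_negated=True)
        assert len(kept) == 1 and kept[0].negated

    def test_planted_corpus_events_equal_gold(self, clean_corpus):
        _, found = run_extraction(clean_corpus)
        found_keys = {
            (
                k,
                e.type,
                e.cause and (e.cause.namespace, e.cause.id),
                (e.theme.namespace, e.theme.id),
            )
            for k, e in found
        }
        gold_keys = {
            (
                k,
                d["type"],
                d["cause"] and (d["cause"].namespace, d["cause"].id),
                (d["theme"].namespace, d["theme"].id),
            )
            for k, d in clean_corpus.gold_events
        }
        assert found_keys == gold_keys


class TestEvaluateRecall:
    def _mention(self, i):
        return (
            0,
            __import__("belflow.extraction", fromlist=["Mention"]).Mention(
                (i, i + 4), f"GEN{i}", "HGNC", f"GEN{i}", BelClass.gene_protein
            ),
        )

    def test_self_recall_is_100(self, clean_corpus):
        gold = clean_corpus.gold_mentions
        report = evaluate_recall(gold, gold)
        assert report.overall_recall == 100.0
        for ns in report.per_namespace.values():
            assert ns["recall"] == 100.0

    def test_recall_definition_with_spurious_finds(self):
        gold = [self._mention(i) for i in range(4)]
        found = gold[:3] + [self._mention(10), self._mention(20)]
        report = evaluate_recall(found, gold)
        assert report.overall_recall == 75.0
        assert report.overall_precision == 60.0

    def test_empty_gold_namespace_errors(self):
        gold = [self._mention(0)]
        with pytest.raises(ValueError, match="no gold mentions"):
            evaluate_recall(gold, gold, namespaces=["CHEBI"])

    @settings(derandomize=True, max_examples=50)
    @given(st.sets(st.integers(min_value=0, max_value=500), min_size=1))
    def test_self_recall_property(self, offsets):
        gold = [self._mention(i) for i in offsets]
        assert evaluate_recall(gold, gold).overall_recall == 100.0

    def test_end_to_end_recall_clean_and_withheld(self):
        clean = generate_corpus(GeneratorConfig(seed=21, n_articles=12))
        found, _ = run_extraction(clean)
        assert evaluate_recall(found, clean.gold_mentions).overall_recall == 100.0

        degraded = generate_corpus(
            GeneratorConfig(seed=21, n_articles=12, withheld_synonym_rate=0.1)
        )
        found_d, _ = run_extraction(degraded)
        recall = evaluate_recall(found_d, degraded.gold_mentions).overall_recall
        assert 84.0 <= recall <= 96.0  # 90% planted rate +/- sampling error
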