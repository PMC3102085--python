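"""Dictionary, finite-state rules, and the n-gram chemical-word scorer."""

import pytest

from chemner.evaluation import evaluate
from chemner.memm import tag
from chemner.pattern import (ChemicalLexicon, build_scorer, default_rules,
                             recognise, score_word)
from chemner.tokeniser import tokenise

ENGLISH = ["the", "reaction", "was", "stirred", "mixture", "sample",
           "solution", "observed", "product", "yield", "under", "with"]
CHEMICALS = ["aztreonam", "methylhexanol", "dichloroethane", "penicillin",
             "bipyridine", "phenanthroline", "diimine", "monodentate"]


@pytest.fixture(scope="module")
def scorer():
    return build_scorer(CHEMICALS, ENGLISH)


class TestScorer:
    def test_mle_dominates_under_small_alpha(self):
        s = build_scorer(["aa"], ["bb"], order=1, smoothing=1e-6)
        # training list {"aa"}: unigram counts a:2, $:1, so the smoothed
        # conditional P(a) must sit at the MLE value 2/3 up to O(alpha)
        p_a = (s.chem_counts[""]["a"] + s.alpha) / (
            s.chem_totals[""] + s.alpha * s.n_outcomes)
        assert p_a == pytest.approx(2 / 3, abs=1e-5)
        assert score_word(s, "aa") > 0

    def test_build_is_deterministic(self):
        a = build_scorer(CHEMICALS, ENGLISH)
        b = build_scorer(CHEMICALS, ENGLISH)
        assert a.chem_counts == b.chem_counts
        assert a.nonchem_counts == b.nonchem_counts

    def test_context_rows_sum_to_one(self, scorer):
        """Direct summation oracle over alphabet + end + unknown."""
        for counts, totals in ((scorer.chem_counts, scorer.chem_totals),
                               (scorer.nonchem_counts, scorer.nonchem_totals)):
            for ctx in list(counts)[:20]:
                V = scorer.n_outcomes
                t = totals[ctx]
                total_p = sum(
                    (counts[ctx].get(ch, 0) + scorer.alpha)
                    / (t + scorer.alpha * V)
                    for ch in set(scorer.alphabet) | {"$", "\x00"})
                assert total_p == pytest.approx(1.0, abs=1e-9)

    def test_training_words_score_positive(self, scorer):
        for w in CHEMICALS:
            assert score_word(scorer, w) > 0

    def test_identical_lists_score_zero(self):
        s = build_scorer(ENGLISH, ENGLISH)
        assert score_word(s, "anything") == pytest.approx(0.0, abs=1e-12)

    def test_swapping_lists_negates_score_exactly(self):
        fwd = build_scorer(CHEMICALS, ENGLISH)
        rev = build_scorer(ENGLISH, CHEMICALS)
        for w in ("aztreonam", "stirred", "xylophone"):
            assert score_word(fwd, w) == pytest.approx(-score_word(rev, w),
                                                       abs=1e-12)

    def test_empty_inputs_rejected(self, scorer):
        with pytest.raises(ValueError):
            build_scorer([], ENGLISH)
        with pytest.raises(ValueError):
            score_word(scorer, "")


class TestRecognise:
    def test_dictionary_single_word(self):
        lex = ChemicalLexicon.from_words(["aztreonam"])
        toks = tokenise("the aztreonam dose")
        ents = recognise(toks, lex)
        assert [(e.surface, e.provenance) for e in ents] == \
            [("aztreonam", "dictionary")]

    def test_multiword_dictionary_match_beats_prefix(self):
        text = "we saw ruthenium (ii) diimine here"
        lex = ChemicalLexicon.from_words(
            ["ruthenium (ii) diimine", "ruthenium (ii)"])
        ents = recognise(tokenise(text), lex, text=text)
        assert [e.surface for e in ents] == ["ruthenium (ii) diimine"]

    def test_sentence_initial_capital_falls_back(self):
        lex = ChemicalLexicon.from_words(["aztreonam"])
        text = "Aztreonam was given."
        ents = recognise(tokenise(text), lex, text=text)
        assert [e.surface for e in ents] == ["Aztreonam"]

    def test_empty_tokens(self):
        lex = ChemicalLexicon.from_words(["x"])
        assert recognise([], lex) == []

    def test_rules_fire_with_provenance(self):
        lex = ChemicalLexicon.from_words(["placeholder"])
        text = "add 2,4-dichlorohexan-1-ol and Cu2+ and β-lactam now"
        ents = recognise(tokenise(text), lex, rules=default_rules(), text=text)
        by_surface = {e.surface: e.provenance for e in ents}
        assert by_surface["2,4-dichlorohexan-1-ol"] == "rule:locant_substituent"
        assert by_surface["Cu2+"] == "rule:formula_charge"
        assert by_surface["β-lactam"] == "rule:greek_hyphenated"

    def test_metal_complex_rule_spans_three_tokens(self):
        lex = ChemicalLexicon.from_words(["placeholder"])
        text = "the ruthenium (ii) diimine complex"
        ents = recognise(tokenise(text), lex, rules=default_rules(), text=text)
        assert ents[0].surface == "ruthenium (ii) diimine"
        assert ents[0].provenance == "rule:metal_complex"

    def test_stop_words_suppress_scorer_only(self):
        """Hand-enumerated resolution on a 4-token fixture: the stop word
        kills its scorer candidate but not the dictionary or rule matches."""
        scorer = build_scorer(["diimine", "diamine", "dioxine"],
                              ["was", "the", "product"])
        lex = ChemicalLexicon.from_words(["aztreonam"],
                                         stop=["diimine", "aztreonam2"])
        text = "aztreonam diimine Cu2+ dioxine"
        ents = recognise(tokenise(text), lex, scorer=scorer,
                         rules=default_rules(), text=text)
        got = {e.surface: e.provenance for e in ents}
        assert got["aztreonam"] == "dictionary"
        assert "diimine" not in got          # scorer-only candidate, stopped
        assert got["Cu2+"] == "rule:formula_charge"  # rule unaffected by stops
        assert got["dioxine"] == "scorer"

    def test_determinism(self):
        scorer = build_scorer(CHEMICALS, ENGLISH)
        lex = ChemicalLexicon.from_words(["aztreonam"], stop=["the"])
        text = "the aztreonam and dichloroethane mix"
        toks = tokenise(text)
        a = recognise(toks, lex, scorer=scorer, rules=default_rules(), text=text)
        b = recognise(toks, lex, scorer=scorer, rules=default_rules(), text=text)
        assert [(e.key(), e.provenance) for e in a] == \
            [(e.key(), e.provenance) for e in b]

    def test_every_lexicon_window_is_recognised(self):
        lex = ChemicalLexicon.from_words(["caffeine", "quinine"])
        text = "caffeine then quinine then caffeine"
        ents = recognise(tokenise(text), lex, text=text)
        assert [e.surface for e in ents] == ["caffeine", "quinine", "caffeine"]

    def test_outputs_never_overlap(self):
        scorer = build_scorer(CHEMICALS, ENGLISH)
        lex = ChemicalLexicon.from_words(["aztreonam", "aztreonam diimine"])
        text = "aztreonam diimine aztreonam"
        ents = recognise(tokenise(text), lex, scorer=scorer,
                         rules=default_rules(), text=text)
        for a, b in zip(ents, ents[1:]):
            assert a.end <= b.start

    def test_lexicon_stop_overlap_rejected(self):
        with pytest.raises(ValueError):
            ChemicalLexicon.from_words(["x"], stop=["x"])


class TestAgainstMEMM:
    def test_pattern_f_below_memm_f_on_synthetic_corpus(
            self, default_split, trained_memm):
        """The deterministic recogniser trails the trained MEMM — the
        expected ordering of the two recogniser families."""
        train_docs, test_docs = default_split
        chem_words = {" ".join(e.surface.split())
                      for d in train_docs for e in d.entities}
        nonchem = {t.surface.lower() for d in train_docs
                   for t in tokenise(d.document)}
        ent_tokens = {w for phrase in chem_words for w in phrase.split()}
        nonchem -= {w.lower() for w in ent_tokens}
        scorer = build_scorer(sorted(ent_tokens), sorted(nonchem))
        lex = ChemicalLexicon.from_words(chem_words)
        gold, pat_pred, memm_pred = [], [], []
        for adoc in test_docs:
            toks = tokenise(adoc.document)
            gold.append(adoc.entities)
            pat_pred.append(recognise(toks, lex, scorer=scorer,
                                      rules=default_rules(),
                                      text=adoc.document.text))
            memm_pred.append(tag(trained_memm, toks, 0.3,
                                 text=adoc.document.text))
        pat_f = evaluate(gold, pat_pred).f_score
        memm_f = evaluate(gold, memm_pred).f_score
        assert pat_f < memm_f
        assert pat_f > 0.2  # the pattern recogniser is still a real system
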