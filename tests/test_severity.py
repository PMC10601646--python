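"""Symptom matching, modifier rules, tonality, and severity aggregation."""

from __future__ import annotations

import pytest

from pfdd.severity import (
    DEFAULT_SYMPTOMS,
    ModifierLexicon,
    SymptomTaxonomy,
    apply_modifiers,
    aspect_polarity,
    classify_tonality,
    match_symptoms,
    score_posts,
    severity_report,
    split_sentences,
)
from tests.conftest import make_post


class ConstantSentiment:
    def __init__(self, value):
        self.value = value

    def polarity(self, text, aspect_span):
        return self.value


# -- taxonomy / matching -------------------------------------------------------


def test_default_taxonomy_size_and_uniqueness():
    tax = SymptomTaxonomy()
    assert len(tax.symptoms) == 20
    assert len(set(tax.symptoms)) == 20


def test_match_case_insensitive_word_boundary():
    tax = SymptomTaxonomy(symptoms=("fatigue", "persistent cough"))
    text = "FATIGUE again; persistent cough too, but not fatigued."
    matches = match_symptoms(text, tax)
    assert [m[0] for m in matches] == ["fatigue", "persistent cough"]


def test_longest_match_wins_on_overlap():
    tax = SymptomTaxonomy(symptoms=("change in voice", "hoarseness in voice"))
    matches = match_symptoms("noticed a change in voice lately", tax)
    assert matches == [("change in voice", (10, 25))]


def test_synonyms_resolve_to_canonical():
    tax = SymptomTaxonomy(symptoms=("fatigue",), synonyms={"wiped out": "fatigue"})
    matches = match_symptoms("feeling wiped out daily", tax)
    assert [m[0] for m in matches] == ["fatigue"]
    with pytest.raises(ValueError, match="unknown symptoms"):
        SymptomTaxonomy(symptoms=("fatigue",), synonyms={"x": "nonexistent"})


# -- sentences / aspect polarity -----------------------------------------------


def test_split_sentences_spans():
    text = "One here. Two there! Three?"
    spans = split_sentences(text)
    assert [text[s:e] for s, e in spans] == ["One here.", "Two there!", "Three?"]


def test_aspect_polarity_is_sentence_scoped(sentiment_backend):
    text = "Everything awful elsewhere. My fatigue is mild."
    span = (text.index("fatigue"), text.index("fatigue") + len("fatigue"))
    p = aspect_polarity(text, span, sentiment_backend)
    assert p == pytest.approx(0.3)  # only "mild" from the containing sentence


def test_aspect_polarity_validates_span(sentiment_backend):
    with pytest.raises(ValueError):
        aspect_polarity("short", (3, 99), sentiment_backend)


# -- modifiers -----------------------------------------------------------------

LEX = ModifierLexicon()


def _span(text, phrase):
    i = text.index(phrase)
    return (i, i + len(phrase))


def test_negation_flips_sign():
    text = "my cough is not terrible today"
    assert apply_modifiers(-0.6, text, _span(text, "cough"), LEX) == pytest.approx(0.6)


def test_double_negation_cancels():
    text = "never not tired from my cough"
    assert apply_modifiers(-0.6, text, _span(text, "cough"), LEX) == pytest.approx(-0.6)


def test_degree_scaling_comparative_and_superlative():
    text1 = "the cough got worse today"
    assert apply_modifiers(-0.4, text1, _span(text1, "cough"), LEX) == pytest.approx(-0.5)
    text2 = "the worst cough ever"
    assert apply_modifiers(-0.4, text2, _span(text2, "cough"), LEX) == pytest.approx(-0.6)


def test_slang_and_emoticon_additive():
    text = "this cough sucks :("
    # -0.4 + (-0.3 slang) + (-0.3 emoticon)
    assert apply_modifiers(-0.4, text, _span(text, "cough"), LEX) == pytest.approx(-1.0)


def test_rule_order_negation_then_degree():
    # flip first (-0.4 -> 0.4), then degree x1.25 -> 0.5; degree-then-flip
    # would give the same magnitude but asserts the documented composition.
    text = "not worse cough today"
    assert apply_modifiers(-0.4, text, _span(text, "cough"), LEX) == pytest.approx(0.5)


def test_scope_window_limits_modifiers():
    text = "not " + "filler " * 6 + "cough here"
    # "not" sits 7 tokens before the mention, outside the 5-token window
    assert apply_modifiers(-0.4, text, _span(text, "cough"), LEX) == pytest.approx(-0.4)


def test_clamping_and_validation():
    text = "worst cough sucks :( :'("
    out = apply_modifiers(-0.9, text, _span(text, "cough"), LEX)
    assert out == -1.0
    with pytest.raises(ValueError):
        apply_modifiers(1.5, text, _span(text, "cough"), LEX)


# -- tonality ------------------------------------------------------------------


@pytest.mark.parametrize(
    "polarity,expected",
    [(-0.2, "negative"), (-0.05, "neutral"), (0.0, "neutral"), (0.05, "neutral"), (0.2, "positive")],
)
def test_tonality_dead_zone(polarity, expected):
    assert classify_tonality(polarity) == expected


def test_tonality_threshold_validation():
    with pytest.raises(ValueError):
        classify_tonality(0.0, thresholds=(0.1, 0.1))


# -- aggregation ---------------------------------------------------------------


def test_severity_counts_distinct_posts_not_mentions():
    tax = SymptomTaxonomy(symptoms=("fatigue", "ear infection"))
    posts = [
        make_post("p1", "My fatigue is bad. This fatigue again, fatigue!"),
        make_post("p2", "fatigue once more"),
        make_post("p3", "ear infection fine actually"),
    ]
    mentions = score_posts(posts, tax, ConstantSentiment(-0.5))
    report = severity_report(mentions)
    assert report.mention_counts == {"fatigue": 4, "ear infection": 1}
    assert report.severities == {"fatigue": 2, "ear infection": 1}  # posts, not mentions


def test_severity_ranking_and_ties():
    tax = SymptomTaxonomy(symptoms=("fatigue", "ear infection", "persistent cough"))
    posts = [
        make_post("p1", "fatigue and ear infection"),
        make_post("p2", "fatigue and persistent cough"),
    ]
    mentions = score_posts(posts, tax, ConstantSentiment(-0.5))
    report = severity_report(mentions, top_n=2)
    assert report.ranking == ("fatigue", "ear infection", "persistent cough")
    assert report.top == (("fatigue", 2), ("ear infection", 1))
    rows = report.to_rows()
    assert rows[0] == {"symptom": "fatigue", "mentions": 2, "severity": 2, "rank": 1}


def test_positive_mentions_do_not_count_toward_severity():
    tax = SymptomTaxonomy(symptoms=("fatigue",))
    posts = [make_post("p1", "fatigue is improving")]
    mentions = score_posts(posts, tax, ConstantSentiment(0.6))
    report = severity_report(mentions)
    assert report.mention_counts == {"fatigue": 1}
    assert report.severities == {"fatigue": 0}


def test_lexicon_from_file(tmp_path):
    path = tmp_path / "lex.json"
    path.write_text('{"scope_window": 2, "negation_cues": ["nope"]}')
    lex = ModifierLexicon.from_file(path)
    assert lex.scope_window == 2 and lex.negation_cues == ("nope",)
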