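"""Corpus I/O and five-step preprocessing."""

from __future__ import annotations

import pytest

from pfdd.corpus import (
    CorpusFormatError,
    KeywordQuery,
    PIIPatterns,
    PreprocessConfig,
    PreprocessReport,
    SocialPost,
    Source,
    apply_query,
    filter_sources,
    load_corpus,
    parse_source,
    preprocess,
    save_corpus,
    scrub_pii,
    scrub_text,
    strip_mentions,
    PII_PLACEHOLDER,
)
from tests.conftest import make_post


# -- source parsing ----------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Twitter updates", Source.TWITTER_UPDATE),
        ("FORUMS", Source.FORUM),
        ("Blog Posts", Source.BLOG_POST),
        ("print news", Source.PRINT_NEWS),
        ("twitter_reply", Source.TWITTER_REPLY),
        ("Quora answers", Source.QUORA_ANSWER),
    ],
)
def test_parse_source_aliases(raw, expected):
    src, recognized = parse_source(raw)
    assert src is expected and recognized


def test_parse_source_unknown_maps_to_other():
    src, recognized = parse_source("carrier pigeon")
    assert src is Source.OTHER and not recognized


def test_is_twitter_property():
    assert Source.TWITTER_UPDATE.is_twitter
    assert Source.TWITTER_REPLY.is_twitter
    assert not Source.FORUM.is_twitter


# -- I/O ---------------------------------------------------------------------


def test_roundtrip_jsonl_and_csv(tmp_path):
    posts = [
        make_post("a", "first post", Source.FORUM, country="US"),
        make_post("b", 'quoted, "text" with commas', Source.TWITTER_UPDATE),
    ]
    for name in ("c.jsonl", "c.csv"):
        path = tmp_path / name
        save_corpus(posts, path)
        loaded = load_corpus(path)
        assert loaded == posts


def test_load_corpus_missing_fields_reports_line_numbers(tmp_path):
    path = tmp_path / "bad.jsonl"
    path.write_text('{"post_id": "a", "text": "ok"}\n{"post_id": "b"}\n')
    with pytest.raises(CorpusFormatError, match="line 2"):
        load_corpus(path)


def test_load_corpus_duplicate_ids(tmp_path):
    path = tmp_path / "dup.jsonl"
    path.write_text('{"post_id": "a", "text": "x"}\n{"post_id": "a", "text": "y"}\n')
    with pytest.raises(CorpusFormatError, match="duplicate"):
        load_corpus(path)


def test_load_csv_requires_columns(tmp_path):
    path = tmp_path / "no_text.csv"
    path.write_text("post_id,source\na,forum\n")
    with pytest.raises(CorpusFormatError, match="text"):
        load_corpus(path)


# -- keyword query -----------------------------------------------------------


def test_query_any_vs_all():
    q_any = KeywordQuery(include_terms=("head and neck", "esophageal"))
    q_all = KeywordQuery(include_terms=("head and neck", "cancer"), match_mode="all_include")
    assert q_any.matches("esophageal concerns")
    assert not q_all.matches("head and neck only")
    assert q_all.matches("head and neck cancer story")


def test_query_exclusion_dominates():
    q = KeywordQuery(include_terms=("cancer",), exclude_terms=("zodiac",))
    assert q.matches("cancer treatment")
    assert not q.matches("cancer zodiac sign")


def test_query_word_boundaries_and_case():
    q = KeywordQuery(include_terms=("cough",))
    assert q.matches("A COUGH again")
    assert not q.matches("coughing")  # whole-phrase only


# -- source filtering --------------------------------------------------------


def test_filter_sources_counts():
    posts = [
        make_post("a", "x", Source.FORUM),
        make_post("b", "x", Source.PRINT_NEWS),
        make_post("c", "x", Source.BLOG_POST, sub_source="YahooFinance"),
    ]
    kept, frag = filter_sources(posts, {Source.PRINT_NEWS}, {"yahoofinance"})
    assert [p.post_id for p in kept] == ["a"]
    assert frag == {"dropped_by_source": 1, "dropped_by_sub_source": 1}


# -- PII ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,n",
    [
        ("write to mary.jones@example.com now", 1),
        ("call 555-0142 or (555) 014-2288", 2),
        ("zip 90210 and postcode SW1A 1AA", 2),
        ("nothing private here", 0),
        ("version 1.2 costs $5", 0),  # short digit runs are not phones
    ],
)
def test_scrub_text_patterns(text, n):
    out, count = scrub_text(text, PIIPatterns())
    assert count == n
    assert out.count(PII_PLACEHOLDER) == n


def test_scrub_gazetteer_names_case_insensitive():
    pats = PIIPatterns(name_gazetteer=("John Smith",))
    out, n = scrub_text("met JOHN SMITH yesterday", pats)
    assert n == 1 and PII_PLACEHOLDER in out


def test_scrub_pii_idempotent():
    pats = PIIPatterns(name_gazetteer=("John Smith",))
    post = make_post(text="email a@b.co, call 555-014-2288, met John Smith")
    once = scrub_pii(post, pats)
    twice = scrub_pii(once, pats)
    assert once == twice
    assert "a@b.co" not in once.text and "John Smith" not in once.text


# -- mentions ----------------------------------------------------------------


def test_strip_mentions_twitter_only():
    tweet = make_post(text="@friend thanks for this", source=Source.TWITTER_UPDATE)
    forum = make_post(text="@friend thanks for this", source=Source.FORUM)
    assert strip_mentions(tweet).text == "thanks for this"
    assert strip_mentions(forum).text == "@friend thanks for this"


def test_strip_mentions_preserves_emails():
    tweet = make_post(text="mail me a@b.co @handle", source=Source.TWITTER_REPLY)
    assert strip_mentions(tweet).text == "mail me a@b.co"


# -- five-step preprocess ----------------------------------------------------


def _config(**kw):
    return PreprocessConfig(
        blocked_sources=frozenset({Source.PRINT_NEWS}),
        blocked_sub_sources=frozenset({"yahoofinance"}),
        pii_patterns=PIIPatterns(name_gazetteer=("John Smith",)),
        **kw,
    )


def test_preprocess_order_and_conservation():
    posts = [
        make_post("keep", "clean forum post", Source.FORUM),
        make_post("news", "from the paper", Source.PRINT_NEWS),
        make_post("sub", "finance take", Source.REVIEW, sub_source="YahooFinance"),
        make_post("pii", "call 555-014-2288 ok", Source.FORUM),
        make_post("tweet", "@x @y hello", Source.TWITTER_UPDATE),
    ]
    clean, report = preprocess(posts, _config())
    assert report.input == 5
    assert report.dropped_by_source == 1
    assert report.dropped_by_sub_source == 1
    assert report.pii_spans_removed == 1
    assert report.mentions_removed == 2
    assert report.output == len(clean) == 3
    report.validate()  # conservation holds
    by_id = {p.post_id: p for p in clean}
    assert by_id["tweet"].text == "hello"
    assert PII_PLACEHOLDER in by_id["pii"].text


def test_preprocess_drops_emptied_posts():
    posts = [make_post("only_mentions", "@a @b", Source.TWITTER_UPDATE)]
    clean, report = preprocess(posts, PreprocessConfig())
    assert clean == []
    assert report.dropped_empty == 1
    report.validate()


def test_preprocess_idempotent():
    posts = [
        make_post("a", "call 555-014-2288 @x thanks", Source.TWITTER_UPDATE),
        make_post("b", "regular post", Source.FORUM),
    ]
    config = _config()
    once, r1 = preprocess(posts, config)
    twice, r2 = preprocess(once, config)
    assert once == twice
    assert r2.pii_spans_removed == 0 and r2.mentions_removed == 0


def test_report_validate_rejects_violation():
    r = PreprocessReport(input=3, output=3, dropped_by_source=1)
    with pytest.raises(ValueError, match="conservation"):
        r.validate()


def test_query_step_counts():
    posts = [
        make_post("a", "head and neck cancer", Source.FORUM),
        make_post("b", "unrelated chatter", Source.FORUM),
    ]
    config = PreprocessConfig(query=KeywordQuery(include_terms=("cancer",)))
    clean, report = preprocess(posts, config)
    assert [p.post_id for p in clean] == ["a"]
    assert report.dropped_by_query == 1


def test_social_post_requires_text():
    with pytest.raises(ValueError):
        SocialPost(post_id="x", text="")
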