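"""Post corpus I/O and cleaning.

Social-media listening corpora arrive as flat CSV/JSONL exports with one
record per post.  Before any modelling, a five-step cleaning sequence is
applied: (1) drop posts from irrelevant source types, (2) keep only posts
matching the topic keyword query, (3) scrub personally identifiable
information, (4) drop posts from blocked sub-sources (specific sites),
(5) strip @-mentions from tweets.  Every step is audited in a
:class:`PreprocessReport` so that ``|output| + drops == |input|`` always
holds.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Source",
    "Indication",
    "SocialPost",
    "KeywordQuery",
    "PIIPatterns",
    "PreprocessConfig",
    "PreprocessReport",
    "CorpusFormatError",
    "load_corpus",
    "save_corpus",
    "filter_sources",
    "apply_query",
    "scrub_pii",
    "strip_mentions",
    "preprocess",
    "PII_PLACEHOLDER",
]

PII_PLACEHOLDER = "[PII]"


class Source(str, Enum):
    """Post origin type, as reported by social-media listening platforms."""

    FORUM = "forum"
    BLOG_POST = "blog_post"
    TWITTER_UPDATE = "twitter_update"
    TWITTER_REPLY = "twitter_reply"
    TWITTER_MENTION = "twitter_mention"
    REVIEW = "review"
    REDDIT_POST = "reddit_post"
    WORDPRESS_POST = "wordpress_post"
    WORDPRESS_COMMENT = "wordpress_comment"
    QUORA_ANSWER = "quora_answer"
    QUORA_COMMENT = "quora_comment"
    BLOG_COMMENT = "blog_comment"
    PODCAST_MESSAGE = "podcast_message"
    CLASSIFIED_MESSAGE = "classified_message"
    PRINT_NEWS = "print_news"
    OTHER = "other"

    @property
    def is_twitter(self) -> bool:
        return self.value.startswith("twitter_")


def _normalize_source_string(raw: str) -> str:
    s = raw.lower().replace("®", "")  # strip (R) marks
    s = re.sub(r"[^a-z0-9]+", " ", s).strip()
    return s


# Verbatim platform source names mapped onto the enum.  Keys are
# normalized with _normalize_source_string.
_SOURCE_ALIASES: dict[str, Source] = {
    "twitter updates": Source.TWITTER_UPDATE,
    "twitter update": Source.TWITTER_UPDATE,
    "twitter replies": Source.TWITTER_REPLY,
    "twitter reply": Source.TWITTER_REPLY,
    "twitter mentions": Source.TWITTER_MENTION,
    "twitter mention": Source.TWITTER_MENTION,
    "twitter": Source.TWITTER_UPDATE,
    "forums": Source.FORUM,
    "forum": Source.FORUM,
    "blog posts": Source.BLOG_POST,
    "blog post": Source.BLOG_POST,
    "blog comments": Source.BLOG_COMMENT,
    "blog comment": Source.BLOG_COMMENT,
    "print news": Source.PRINT_NEWS,
    "review types": Source.REVIEW,
    "reviews": Source.REVIEW,
    "review": Source.REVIEW,
    "reddit posts": Source.REDDIT_POST,
    "reddit post": Source.REDDIT_POST,
    "wordpress posts": Source.WORDPRESS_POST,
    "wordpress post": Source.WORDPRESS_POST,
    "wordpress comments": Source.WORDPRESS_COMMENT,
    "wordpress comment": Source.WORDPRESS_COMMENT,
    "quora answers": Source.QUORA_ANSWER,
    "quora answer": Source.QUORA_ANSWER,
    "quora comments": Source.QUORA_COMMENT,
    "quora comment": Source.QUORA_COMMENT,
    "podcast messages": Source.PODCAST_MESSAGE,
    "podcast message": Source.PODCAST_MESSAGE,
    "classified messages": Source.CLASSIFIED_MESSAGE,
    "classified message": Source.CLASSIFIED_MESSAGE,
    "other": Source.OTHER,
}
# Enum values map to themselves.
_SOURCE_ALIASES.update({s.value.replace("_", " "): s for s in Source})


def parse_source(raw: str) -> tuple[Source, bool]:
    """Map a raw source string to the enum.

    Returns ``(source, recognized)``; unrecognized strings map to
    :attr:`Source.OTHER` with ``recognized=False``.
    """
    key = _normalize_source_string(raw)
    if key in _SOURCE_ALIASES:
        return _SOURCE_ALIASES[key], True
    return Source.OTHER, False


class Indication(str, Enum):
    HEAD_AND_NECK = "head_and_neck"
    ESOPHAGEAL = "esophageal"
    OTHER = "other"


@dataclass(frozen=True, slots=True)
class SocialPost:
    """One social-media post with listening-platform metadata."""

    post_id: str
    text: str
    source: Source = Source.OTHER
    sub_source: str = ""
    country: str = "unknown"
    date: str = ""
    indication: Indication = Indication.OTHER

    def __post_init__(self) -> None:
        if not self.post_id:
            raise ValueError("post_id must be non-empty")
        if not self.text:
            raise ValueError(f"post {self.post_id!r}: text must be non-empty")

    def to_record(self) -> dict[str, str]:
        return {
            "post_id": self.post_id,
            "source": self.source.value,
            "sub_source": self.sub_source,
            "text": self.text,
            "country": self.country,
            "date": self.date,
            "indication": self.indication.value,
        }


class CorpusFormatError(ValueError):
    """A corpus file violates the expected schema."""


_REQUIRED_FIELDS = ("post_id", "text")
_ALL_FIELDS = ("post_id", "source", "sub_source", "text", "country", "date", "indication")


def _post_from_record(rec: dict, lineno: int, errors: list[str]) -> SocialPost | None:
    missing = [f for f in _REQUIRED_FIELDS if not str(rec.get(f, "") or "").strip()]
    if missing:
        errors.append(f"line {lineno}: missing field(s) {', '.join(missing)}")
        return None
    source, _ = parse_source(str(rec.get("source", "other") or "other"))
    try:
        indication = Indication(str(rec.get("indication", "other") or "other"))
    except ValueError:
        indication = Indication.OTHER
    return SocialPost(
        post_id=str(rec["post_id"]),
        text=str(rec["text"]),
        source=source,
        sub_source=str(rec.get("sub_source", "") or ""),
        country=str(rec.get("country", "unknown") or "unknown"),
        date=str(rec.get("date", "") or ""),
        indication=indication,
    )


def load_corpus(path: str | Path, format: str | None = None) -> list[SocialPost]:
    """Read a corpus from CSV (header required) or JSONL.

    ``format`` is inferred from the suffix when omitted.  Records with a
    missing ``post_id`` or ``text`` raise :class:`CorpusFormatError`
    listing the offending line numbers; unknown source strings map to
    ``other``.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unsupported corpus format: {format!r}")

    posts: list[SocialPost] = []
    errors: list[str] = []
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing_cols = [c for c in _REQUIRED_FIELDS if c not in header]
            if missing_cols:
                raise CorpusFormatError(
                    f"{path}: missing required column(s): {', '.join(missing_cols)}"
                )
            for lineno, rec in enumerate(reader, start=2):
                post = _post_from_record(rec, lineno, errors)
                if post is not None:
                    posts.append(post)
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    errors.append(f"line {lineno}: invalid JSON ({exc.msg})")
                    continue
                post = _post_from_record(rec, lineno, errors)
                if post is not None:
                    posts.append(post)
    if errors:
        raise CorpusFormatError(f"{path}: " + "; ".join(errors))

    seen: set[str] = set()
    for p in posts:
        if p.post_id in seen:
            raise CorpusFormatError(f"{path}: duplicate post_id {p.post_id!r}")
        seen.add(p.post_id)
    return posts


def save_corpus(posts: Iterable[SocialPost], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_ALL_FIELDS))
            writer.writeheader()
            for p in posts:
                writer.writerow(p.to_record())
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for p in posts:
                fh.write(json.dumps(p.to_record(), sort_keys=True) + "\n")
    else:
        raise ValueError(f"unsupported corpus format: {format!r}")


# ---------------------------------------------------------------------------
# Keyword query


@dataclass(frozen=True)
class KeywordQuery:
    """Boolean include/exclude phrase query.

    A post matches iff the include condition holds (any or all of
    ``include_terms``, per ``match_mode``) and no exclude term matches.
    Matching is case-insensitive, whole-phrase, on word boundaries.
    """

    include_terms: tuple[str, ...]
    exclude_terms: tuple[str, ...] = ()
    match_mode: str = "any_include"  # or "all_include"

    def __post_init__(self) -> None:
        if not self.include_terms:
            raise ValueError("include_terms must be non-empty")
        if self.match_mode not in ("any_include", "all_include"):
            raise ValueError(f"unknown match_mode: {self.match_mode!r}")

    @staticmethod
    def _phrase_re(phrase: str) -> re.Pattern[str]:
        return re.compile(r"(?<!\w)" + re.escape(phrase.strip()) + r"(?!\w)", re.IGNORECASE)

    def matches(self, text: str) -> bool:
        includes = [self._phrase_re(t).search(text) is not None for t in self.include_terms]
        ok = any(includes) if self.match_mode == "any_include" else all(includes)
        if not ok:
            return False
        return not any(self._phrase_re(t).search(text) for t in self.exclude_terms)


def apply_query(posts: Sequence[SocialPost], query: KeywordQuery) -> list[SocialPost]:
    """Keep posts satisfying the keyword query predicate, order preserved."""
    return [p for p in posts if query.matches(p.text)]


# ---------------------------------------------------------------------------
# Source filtering


def filter_sources(
    posts: Sequence[SocialPost],
    blocked_sources: set[Source] | set[str] | None = None,
    blocked_sub_sources: set[str] | None = None,
) -> tuple[list[SocialPost], dict[str, int]]:
    """Drop posts whose source or sub-source is blocked.

    Returns the kept posts (order preserved) and a report fragment with
    per-reason drop counts.
    """
    blocked_src = {Source(s) for s in (blocked_sources or set())}
    blocked_sub = {s.lower() for s in (blocked_sub_sources or set())}
    kept: list[SocialPost] = []
    dropped_by_source = 0
    dropped_by_sub_source = 0
    for p in posts:
        if p.source in blocked_src:
            dropped_by_source += 1
        elif p.sub_source.lower() in blocked_sub:
            dropped_by_sub_source += 1
        else:
            kept.append(p)
    return kept, {
        "dropped_by_source": dropped_by_source,
        "dropped_by_sub_source": dropped_by_sub_source,
    }


# ---------------------------------------------------------------------------
# PII scrubbing

_EMAIL_RE = re.compile(r"\b[\w.+-]+@[\w-]+(?:\.[\w-]+)+\b")
# Phone-like runs: 7+ digits allowing separators, optional leading +.
_PHONE_RE = re.compile(r"(?<![\w.])\+?\d(?:[\s().-]?\d){6,14}(?![\w.])")
# US ZIP / ZIP+4 and UK-style postcodes.
_POSTAL_RE = re.compile(
    r"\b(?:\d{5}(?:-\d{4})?|[A-Z]{1,2}\d[A-Z\d]?\s?\d[A-Z]{2})\b"
)


@dataclass(frozen=True)
class PIIPatterns:
    """PII matchers: emails, phone digit runs, postal codes, a name gazetteer."""

    name_gazetteer: tuple[str, ...] = ()
    extra_patterns: tuple[str, ...] = ()

    def compiled(self) -> list[re.Pattern[str]]:
        pats = [_EMAIL_RE, _PHONE_RE, _POSTAL_RE]
        if self.name_gazetteer:
            names = sorted(self.name_gazetteer, key=len, reverse=True)
            pats.append(
                re.compile(
                    r"\b(?:" + "|".join(re.escape(n) for n in names) + r")\b",
                    re.IGNORECASE,
                )
            )
        pats.extend(re.compile(p) for p in self.extra_patterns)
        return pats


def scrub_text(text: str, patterns: PIIPatterns) -> tuple[str, int]:
    """Replace every PII span with the fixed placeholder; count replacements."""
    n = 0
    for pat in patterns.compiled():
        text, k = pat.subn(PII_PLACEHOLDER, text)
        n += k
    return text, n


def scrub_pii(post: SocialPost, patterns: PIIPatterns) -> SocialPost:
    """Scrub PII from one post, replacing each span with ``[PII]``.

    Idempotent: the placeholder contains no digits or ``@`` so a second
    pass matches nothing.
    """
    text, n = scrub_text(post.text, patterns)
    return post if n == 0 else replace(post, text=text)


# ---------------------------------------------------------------------------
# Mention stripping

# @ not preceded by a word char or dot (keeps emails intact for scrub_pii).
_MENTION_RE = re.compile(r"(?<![\w.@])@\w{1,50}")
_WS_RE = re.compile(r"\s+")


def strip_mentions_text(text: str) -> tuple[str, int]:
    out, n = _MENTION_RE.subn("", text)
    if n:
        out = _WS_RE.sub(" ", out).strip()
    return out, n


def strip_mentions(post: SocialPost) -> SocialPost:
    """Remove @handle tokens from twitter-sourced posts; normalize whitespace.

    Non-twitter sources pass through unchanged (their @-bearing tokens,
    e.g. emails, are the PII scrubber's job).
    """
    if not post.source.is_twitter:
        return post
    text, n = strip_mentions_text(post.text)
    return post if n == 0 else replace(post, text=text)


# ---------------------------------------------------------------------------
# Five-step preprocessing


@dataclass(frozen=True)
class PreprocessConfig:
    blocked_sources: frozenset[Source] = frozenset()
    blocked_sub_sources: frozenset[str] = frozenset()
    query: KeywordQuery | None = None
    pii_patterns: PIIPatterns = field(default_factory=PIIPatterns)


@dataclass
class PreprocessReport:
    """Per-step audit counts for one cleaning run."""

    input: int = 0
    dropped_by_source: int = 0
    dropped_by_query: int = 0
    dropped_by_sub_source: int = 0
    dropped_empty: int = 0
    pii_spans_removed: int = 0
    mentions_removed: int = 0
    output: int = 0

    @property
    def total_dropped(self) -> int:
        return (
            self.dropped_by_source
            + self.dropped_by_query
            + self.dropped_by_sub_source
            + self.dropped_empty
        )

    def validate(self) -> None:
        counts = [
            self.input,
            self.dropped_by_source,
            self.dropped_by_query,
            self.dropped_by_sub_source,
            self.dropped_empty,
            self.pii_spans_removed,
            self.mentions_removed,
            self.output,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("report counts must be non-negative")
        if self.output != self.input - self.total_dropped:
            raise ValueError("report conservation violated: output != input - drops")

    def to_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "dropped_by_source": self.dropped_by_source,
            "dropped_by_query": self.dropped_by_query,
            "dropped_by_sub_source": self.dropped_by_sub_source,
            "dropped_empty": self.dropped_empty,
            "pii_spans_removed": self.pii_spans_removed,
            "mentions_removed": self.mentions_removed,
            "output": self.output,
        }


def preprocess(
    posts: Sequence[SocialPost], config: PreprocessConfig
) -> tuple[list[SocialPost], PreprocessReport]:
    """Apply the five cleaning steps in order.

    Order: source filter -> keyword query -> PII scrub -> sub-source
    filter -> mention strip.  Posts whose text becomes empty after
    scrubbing/stripping are dropped and counted, not kept blank.
    Deterministic and idempotent.
    """
    report = PreprocessReport(input=len(posts))

    # 1. source filter
    kept, frag = filter_sources(posts, config.blocked_sources, set())
    report.dropped_by_source = frag["dropped_by_source"]

    # 2. keyword query
    if config.query is not None:
        before = len(kept)
        kept = apply_query(kept, config.query)
        report.dropped_by_query = before - len(kept)

    # 3. PII scrub
    scrubbed: list[SocialPost] = []
    for p in kept:
        text, n = scrub_text(p.text, config.pii_patterns)
        report.pii_spans_removed += n
        stripped = text.strip()
        if not stripped:
            report.dropped_empty += 1
            continue
        scrubbed.append(p if n == 0 else replace(p, text=text))
    kept = scrubbed

    # 4. sub-source filter
    kept, frag = filter_sources(kept, set(), set(config.blocked_sub_sources))
    report.dropped_by_sub_source = frag["dropped_by_sub_source"]

    # 5. mention strip (tweets only)
    final: list[SocialPost] = []
    for p in kept:
        if p.source.is_twitter:
            text, n = strip_mentions_text(p.text)
            report.mentions_removed += n
            if not text.strip():
                report.dropped_empty += 1
                continue
            final.append(p if n == 0 else replace(p, text=text))
        else:
            final.append(p)

    report.output = len(final)
    report.validate()
    return final, report
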