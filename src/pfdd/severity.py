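"""Aspect-based symptom-severity scoring.

Symptom phrases from a fixed clinical taxonomy (head & neck / esophageal
presentations such as "persistent cough" or "hoarseness in voice") are
matched in posts; each mention's tonality is the aspect-conditioned
sentiment of its sentence, adjusted by social-media modifier rules —
negation flips the sign, degree words (comparative / superlative) scale
the magnitude, slang terms and emoticons add signed increments — then
discretized into negative / neutral / positive with a small dead zone.
A symptom's *severity* is the number of distinct posts that discuss it in
negative tonality.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .backends import BackendContractError, SentimentBackend

__all__ = [
    "DEFAULT_SYMPTOMS",
    "SymptomTaxonomy",
    "ModifierLexicon",
    "SymptomMention",
    "SeverityReport",
    "match_symptoms",
    "split_sentences",
    "aspect_polarity",
    "apply_modifiers",
    "classify_tonality",
    "severity_report",
    "score_posts",
]

# Reference presentation taxonomy for head & neck and esophageal cancer.
DEFAULT_SYMPTOMS: tuple[str, ...] = (
    "swelling that does not heal",
    "a sore that does not heal",
    "red patch in the mouth",
    "white patch in the mouth",
    "lump in the head area with pain",
    "foul mouth odor not explained by hygiene",
    "hoarseness in voice",
    "change in voice",
    "nasal obstruction",
    "persistent nasal congestion",
    "unusual nasal discharge",
    "loosening of teeth",
    "dentures that no longer fit",
    "unexplained weight loss",
    "fatigue",
    "ear infection",
    "persistent cough",
    "coughing up blood",
    "feeling there is something stuck in the throat",
    "numbness in the mouth that will not subside",
)


@dataclass(frozen=True)
class SymptomTaxonomy:
    """Canonical symptom phrases with optional synonyms (synonym -> canonical)."""

    symptoms: tuple[str, ...] = DEFAULT_SYMPTOMS
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = tuple(s.strip().lower() for s in self.symptoms)
        if any(not s for s in norm):
            raise ValueError("symptom phrases must be non-empty")
        if len(set(norm)) != len(norm):
            raise ValueError("symptom phrases must be unique")
        object.__setattr__(self, "symptoms", norm)
        syn = {k.strip().lower(): v.strip().lower() for k, v in self.synonyms.items()}
        unknown = [v for v in syn.values() if v not in norm]
        if unknown:
            raise ValueError(f"synonyms map to unknown symptoms: {unknown}")
        object.__setattr__(self, "synonyms", syn)

    def all_phrases(self) -> dict[str, str]:
        """Every matchable phrase -> canonical symptom."""
        phrases = {s: s for s in self.symptoms}
        phrases.update(self.synonyms)
        return phrases

    @classmethod
    def from_file(cls, path: str | Path) -> "SymptomTaxonomy":
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        return cls(
            symptoms=tuple(raw.get("symptoms", ())),
            synonyms=dict(raw.get("synonyms", {})),
        )


@dataclass(frozen=True)
class ModifierLexicon:
    """Modifier rules applied inside a token window around the mention.

    Degree weights multiply the magnitude (superlative > comparative > 1),
    negation cues flip the sign, slang terms and emoticons add signed
    increments; the result is clamped to [-1, 1].
    """

    degree_words: Mapping[str, float] = field(
        default_factory=lambda: {
            "worse": 1.25,
            "better": 1.25,
            "more": 1.25,
            "less": 1.25,
            "worst": 1.5,
            "best": 1.5,
            "most": 1.5,
            "least": 1.5,
        }
    )
    negation_cues: tuple[str, ...] = ("not", "no", "never", "without", "hardly")
    slang_weights: Mapping[str, float] = field(
        default_factory=lambda: {"sucks": -0.3, "meh": -0.2, "lit": 0.3, "yikes": -0.3}
    )
    emoticon_weights: Mapping[str, float] = field(
        default_factory=lambda: {":(": -0.3, ":-(": -0.3, ":'(": -0.4, ":)": 0.3, ":-)": 0.3, ":D": 0.4}
    )
    scope_window: int = 5

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModifierLexicon":
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        kwargs = {}
        for key in ("degree_words", "slang_weights", "emoticon_weights"):
            if key in raw:
                kwargs[key] = dict(raw[key])
        if "negation_cues" in raw:
            kwargs["negation_cues"] = tuple(raw["negation_cues"])
        if "scope_window" in raw:
            kwargs["scope_window"] = int(raw["scope_window"])
        return cls(**kwargs)


@dataclass(frozen=True)
class SymptomMention:
    post_id: str
    symptom: str
    span: tuple[int, int]
    base_polarity: float
    adjusted_polarity: float
    tonality: str  # negative | neutral | positive

    def to_record(self) -> dict:
        return {
            "post_id": self.post_id,
            "symptom": self.symptom,
            "span": list(self.span),
            "base_polarity": self.base_polarity,
            "adjusted_polarity": self.adjusted_polarity,
            "tonality": self.tonality,
        }


@dataclass(frozen=True)
class SeverityReport:
    """Per-symptom mention distribution and negative-post severity ranking."""

    mention_counts: dict[str, int]
    severities: dict[str, int]  # distinct posts with >= 1 negative mention
    ranking: tuple[str, ...]  # all symptoms, by severity desc then name
    top: tuple[tuple[str, int], ...]  # top-N (symptom, severity)

    def to_rows(self) -> list[dict]:
        rank = {s: i + 1 for i, s in enumerate(self.ranking)}
        return [
            {
                "symptom": s,
                "mentions": self.mention_counts.get(s, 0),
                "severity": self.severities.get(s, 0),
                "rank": rank[s],
            }
            for s in self.ranking
        ]


# ---------------------------------------------------------------------------
# Matching


def match_symptoms(text: str, taxonomy: SymptomTaxonomy) -> list[tuple[str, tuple[int, int]]]:
    """Case-insensitive, word-boundary phrase matches; longest match wins on
    overlaps; synonyms resolve to their canonical symptom."""
    phrases = taxonomy.all_phrases()
    candidates: list[tuple[int, int, str]] = []
    for phrase, canonical in phrases.items():
        pat = re.compile(r"(?<!\w)" + re.escape(phrase) + r"(?!\w)", re.IGNORECASE)
        for m in pat.finditer(text):
            candidates.append((m.start(), m.end(), canonical))
    # longest-match-wins: sort by length desc, keep non-overlapping
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    taken: list[tuple[int, int]] = []
    kept: list[tuple[str, tuple[int, int]]] = []
    for start, end, canonical in candidates:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        kept.append((canonical, (start, end)))
    kept.sort(key=lambda k: k[1][0])
    return kept


_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of naive punctuation-delimited sentences."""
    spans = []
    start = 0
    for m in _SENT_SPLIT_RE.finditer(text):
        spans.append((start, m.start()))
        start = m.end()
    spans.append((start, len(text)))
    return spans


def _containing_sentence(text: str, span: tuple[int, int]) -> tuple[int, int]:
    for s, e in split_sentences(text):
        if s <= span[0] < max(e, s + 1):
            return (s, e)
    return (0, len(text))


def aspect_polarity(
    text: str, span: tuple[int, int], backend: SentimentBackend
) -> float:
    """Backend polarity of the sentence containing the mention, conditioned
    on the aspect span (re-indexed into the sentence)."""
    if not (0 <= span[0] < span[1] <= len(text)):
        raise ValueError("mention span outside text")
    s, e = _containing_sentence(text, span)
    sentence = text[s:e]
    local = (span[0] - s, span[1] - s)
    p = backend.polarity(sentence, local)
    if not -1.0 <= p <= 1.0:
        raise BackendContractError(f"sentiment polarity {p} outside [-1, 1]")
    return float(p)


# ---------------------------------------------------------------------------
# Modifier rules

_WORD_RE = re.compile(r"\S+")


def _window_tokens(text: str, span: tuple[int, int], window: int) -> list[str]:
    """Tokens within `window` tokens on either side of the span (span excluded)."""
    tokens = [(m.start(), m.end(), m.group()) for m in _WORD_RE.finditer(text)]
    before = [t for t in tokens if t[1] <= span[0]]
    after = [t for t in tokens if t[0] >= span[1]]
    ctx = before[-window:] + after[:window]
    return [t[2] for t in ctx]


def apply_modifiers(
    base_polarity: float,
    text: str,
    span: tuple[int, int],
    lexicon: ModifierLexicon,
) -> float:
    """Adjust a base polarity using modifier cues near the mention.

    Fixed rule order: negation (sign flip per cue) -> degree
    (multiplicative) -> slang (additive) -> emoticon (additive); the
    result is clamped to [-1, 1].  Texts with no lexicon hits pass
    through unchanged.
    """
    if not -1.0 <= base_polarity <= 1.0:
        raise ValueError("base_polarity outside [-1, 1]")
    raw_tokens = _window_tokens(text, span, lexicon.scope_window)
    words = [t.strip(".,;!?\"'").lower() for t in raw_tokens]
    polarity = base_polarity

    flips = sum(1 for w in words if w in lexicon.negation_cues)
    if flips % 2 == 1:
        polarity = -polarity
    for w in words:
        if w in lexicon.degree_words:
            polarity *= lexicon.degree_words[w]
    for w in words:
        if w in lexicon.slang_weights:
            polarity += lexicon.slang_weights[w]
    for t in raw_tokens:  # emoticons match raw tokens (punctuation matters)
        if t in lexicon.emoticon_weights:
            polarity += lexicon.emoticon_weights[t]
    return max(-1.0, min(1.0, polarity))


def classify_tonality(
    adjusted_polarity: float, thresholds: tuple[float, float] = (-0.05, 0.05)
) -> str:
    """Discretize polarity with a dead zone: < lo negative, > hi positive."""
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must satisfy lo < hi")
    if adjusted_polarity < lo:
        return "negative"
    if adjusted_polarity > hi:
        return "positive"
    return "neutral"


# ---------------------------------------------------------------------------
# Aggregation


def score_posts(
    posts: Iterable,  # SocialPost-like with .post_id and .text
    taxonomy: SymptomTaxonomy,
    backend: SentimentBackend,
    lexicon: ModifierLexicon | None = None,
    thresholds: tuple[float, float] = (-0.05, 0.05),
) -> list[SymptomMention]:
    """Full mention pipeline: match -> aspect polarity -> modifiers -> tonality."""
    lexicon = lexicon or ModifierLexicon()
    mentions: list[SymptomMention] = []
    for post in posts:
        for symptom, span in match_symptoms(post.text, taxonomy):
            base = aspect_polarity(post.text, span, backend)
            adj = apply_modifiers(base, post.text, span, lexicon)
            mentions.append(
                SymptomMention(
                    post_id=post.post_id,
                    symptom=symptom,
                    span=span,
                    base_polarity=base,
                    adjusted_polarity=adj,
                    tonality=classify_tonality(adj, thresholds),
                )
            )
    return mentions


def severity_report(mentions: Sequence[SymptomMention], top_n: int = 10) -> SeverityReport:
    """Severity = number of distinct posts with >= 1 negative mention of the
    symptom; ranking by severity descending, ties by symptom name."""
    mention_counts: dict[str, int] = {}
    negative_posts: dict[str, set[str]] = {}
    for m in mentions:
        mention_counts[m.symptom] = mention_counts.get(m.symptom, 0) + 1
        if m.tonality == "negative":
            negative_posts.setdefault(m.symptom, set()).add(m.post_id)
    severities = {s: len(negative_posts.get(s, set())) for s in mention_counts}
    ranking = tuple(sorted(severities, key=lambda s: (-severities[s], s)))
    top = tuple((s, severities[s]) for s in ranking[:top_n])
    return SeverityReport(
        mention_counts=mention_counts,
        severities=severities,
        ranking=ranking,
        top=top,
    )
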