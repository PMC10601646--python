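"""Seeded synthetic social-media corpora with full ground truth.

Every pipeline stage is exercisable offline: the generator emits posts in
the standard corpus dialect together with a per-post truth record —
audience class, planted PII spans, planted @-mentions, planted symptom
sentences with known tonality, planted medical-sentiment cue phrases
(agreeing or disagreeing across the two hypothesis sets), and planted
psychosocial definition cues.  Texts are template-based over a controlled
vocabulary so cue-overlap arithmetic is exact, which is what makes the
planted-signal recovery tests deterministic.

Two deterministic mock backends live here as well: a cue-overlap NLI
scorer and a lexicon-sum sentiment scorer.  They honor the same contracts
as real transformer backends but run in microseconds on a CPU.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import Indication, SocialPost, Source
from .medsent import HYPOTHESIS_SET_1, HYPOTHESIS_SET_2
from .negative_learning import AUDIENCE_LABELS, LabeledExample, inject_noise
from .psychosocial import default_taxonomy

__all__ = [
    "GeneratorConfig",
    "PostTruth",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_noisy_labels",
    "MockNLIBackend",
    "MockSentimentBackend",
    "mock_nli_backend",
    "mock_sentiment_backend",
    "default_nli_cue_table",
    "DEFAULT_SENTIMENT_LEXICON",
    "DEFAULT_NAME_GAZETTEER",
    "CLASS_CUE_TOKENS",
    "MEDSENT_AGREE_PHRASES",
    "MEDSENT_DISAGREE_PHRASES",
]

# ---------------------------------------------------------------------------
# Controlled vocabulary.  Token pools are mutually disjoint and avoid every
# modifier-lexicon word so planted tonality survives the modifier rules.

_FILLER = (
    "today", "just", "really", "sharing", "thread", "community", "journey",
    "everyone", "morning", "update", "reading", "question", "week", "time",
    "thoughts", "post",
)

CLASS_CUE_TOKENS: dict[str, tuple[str, ...]] = {
    "patient": ("diagnosed", "radiotherapy", "biopsy", "oncologist", "remission", "swallowing"),
    "caregiver": ("husband", "wife", "mother", "caregiver", "appointments", "caring"),
    "irrelevant": ("giveaway", "promo", "crypto", "horoscope", "betting", "discount"),
}

# Medical-sentiment cue phrases.  Agreement phrases contain the cue tokens
# of BOTH hypothesis sets for one class; disagreement phrases mix set-1
# cues of one class with set-2 cues of another, so the two hypothesis sets
# pick different winners.
_SET1_CUES: dict[str, frozenset[str]] = {
    "recovery": frozenset({"improving", "better"}),
    "deteriorating": frozenset({"worse", "declining"}),
    "condition_present": frozenset({"still", "persists"}),
}
_SET2_CUES: dict[str, frozenset[str]] = {
    "recovery": frozenset({"subsided", "healed"}),
    "deteriorating": frozenset({"deteriorating", "failing"}),
    "condition_present": frozenset({"unchanged", "lingering"}),
}

MEDSENT_AGREE_PHRASES: dict[str, str] = {
    "recovery": "I am improving and feeling better since the swelling subsided and healed.",
    "deteriorating": "Things got worse and keep declining, the treatment is failing and everything is deteriorating.",
    "condition_present": "The condition is still there and persists, unchanged and lingering.",
}
# (set1 class, set2 class) -> phrase; set1 and set2 disagree by design.
MEDSENT_DISAGREE_PHRASES: dict[str, tuple[str, str, str]] = {
    "recovery": ("recovery", "deteriorating",
                 "I am improving and feeling better but the treatment is failing and deteriorating."),
    "deteriorating": ("deteriorating", "condition_present",
                      "Things got worse and keep declining yet unchanged and lingering overall."),
    "condition_present": ("condition_present", "recovery",
                          "It is still there and persists although it also subsided and healed once."),
}

DEFAULT_SENTIMENT_LEXICON: dict[str, float] = {
    "unbearable": -0.8,
    "awful": -0.7,
    "terrible": -0.7,
    "painful": -0.6,
    "exhausting": -0.6,
    "relieved": 0.6,
    "manageable": 0.5,
    "improving": 0.6,
    "mild": 0.3,
}

_TONALITY_TEMPLATES: dict[str, str] = {
    "negative": "My {symptom} is awful and unbearable.",
    "neutral": "I read about {symptom} in a leaflet.",
    "positive": "My {symptom} is manageable and improving.",
}

DEFAULT_NAME_GAZETTEER: tuple[str, ...] = ("John Smith", "Mary Jones", "Anita Rao")

_PII_POOL: tuple[str, ...] = (
    "mary.jones@example.com",
    "sam.carter@example.org",
    "555-0142",
    "(555) 014-2288",
    "90210",
    "SW1A 1AA",
    "John Smith",
    "Mary Jones",
)

_MENTION_POOL: tuple[str, ...] = ("@hopefulpatient", "@carejourney", "@oncochat", "@nursejay")

_SOURCE_SUB_SOURCES: dict[Source, tuple[str, ...]] = {
    Source.FORUM: ("cancerforum.org", "healthboards.com"),
    Source.BLOG_POST: ("medium.com", "caringblog.net"),
    Source.TWITTER_UPDATE: ("twitter.com",),
    Source.TWITTER_REPLY: ("twitter.com",),
    Source.REVIEW: ("drugreviews.com", "YahooFinance"),
    Source.REDDIT_POST: ("reddit.com",),
    Source.PRINT_NEWS: ("DailyNews", "YahooFinance"),
    Source.PODCAST_MESSAGE: ("podbay.fm",),
}

_DEFAULT_SOURCE_MIX: dict[Source, float] = {
    Source.FORUM: 0.30,
    Source.BLOG_POST: 0.20,
    Source.TWITTER_UPDATE: 0.25,
    Source.TWITTER_REPLY: 0.05,
    Source.REVIEW: 0.05,
    Source.REDDIT_POST: 0.05,
    Source.PRINT_NEWS: 0.05,
    Source.PODCAST_MESSAGE: 0.05,
}

_DEFAULT_SYMPTOM_PLANTS: dict[str, tuple[int, int, int]] = {
    "fatigue": (6, 2, 2),
    "persistent cough": (4, 1, 1),
    "hoarseness in voice": (3, 1, 0),
    "unexplained weight loss": (5, 0, 1),
    "coughing up blood": (2, 1, 0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``signal_strength`` is the class-conditional cue-token rate: each post
    carries three cue slots, each drawn from its own class's vocabulary
    with this probability and from the pooled vocabulary otherwise, so 0
    yields chance-level separability and values near 1 a nearly separable
    corpus.
    """

    n_posts: int = 1000
    class_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # patient/caregiver/irrelevant
    signal_strength: float = 0.8
    pii_rate: float = 0.10
    mention_rate: float = 0.30  # among twitter posts
    symptom_plants: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_SYMPTOM_PLANTS)
    )
    medsent_rate: float = 0.30
    medsent_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # recovery/deteriorating/present
    medsent_agree_rate: float = 0.7
    psychosocial_rate: float = 0.15
    source_mix: Mapping[Source, float] = field(default_factory=lambda: dict(_DEFAULT_SOURCE_MIX))
    quota_classes: bool = True  # exact class counts (largest remainder) vs multinomial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise ValueError("n_posts must be >= 1")
        for name, mix in (("class_mix", self.class_mix), ("medsent_mix", self.medsent_mix)):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if abs(sum(self.source_mix.values()) - 1.0) > 1e-9:
            raise ValueError("source_mix must sum to 1")
        for name, r in (
            ("signal_strength", self.signal_strength),
            ("pii_rate", self.pii_rate),
            ("mention_rate", self.mention_rate),
            ("medsent_rate", self.medsent_rate),
            ("medsent_agree_rate", self.medsent_agree_rate),
            ("psychosocial_rate", self.psychosocial_rate),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total_plants = sum(sum(v) for v in self.symptom_plants.values())
        if total_plants > self.n_posts:
            raise ValueError("symptom plants exceed n_posts")


@dataclass(frozen=True)
class PostTruth:
    """Ground truth for one synthetic post."""

    audience: str
    pii_spans: tuple[tuple[int, int, str], ...] = ()
    mention_handles: tuple[str, ...] = ()
    symptom: tuple[str, str] | None = None  # (canonical symptom, tonality)
    medsent: str | None = None  # intended class of the planted cue phrase
    medsent_agree: bool | None = None
    psychosocial: tuple[str, str] | None = None  # (label, definition)

    def to_record(self, post_id: str) -> dict:
        return {
            "post_id": post_id,
            "audience": self.audience,
            "pii_spans": [list(s[:2]) + [s[2]] for s in self.pii_spans],
            "mention_handles": list(self.mention_handles),
            "symptom": list(self.symptom) if self.symptom else None,
            "medsent": self.medsent,
            "medsent_agree": self.medsent_agree,
            "psychosocial": list(self.psychosocial) if self.psychosocial else None,
        }


@dataclass(frozen=True)
class SyntheticCorpus:
    posts: tuple[SocialPost, ...]
    truth: Mapping[str, PostTruth]
    config: GeneratorConfig

    def save(self, corpus_path: str | Path, truth_path: str | Path | None = None) -> None:
        from .corpus import save_corpus

        save_corpus(self.posts, corpus_path)
        if truth_path is not None:
            with Path(truth_path).open("w", encoding="utf-8") as fh:
                for p in self.posts:
                    fh.write(
                        json.dumps(self.truth[p.post_id].to_record(p.post_id), sort_keys=True)
                        + "\n"
                    )


def _quota_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items to len(mix) bins."""
    raw = [n * m for m in mix]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Deterministic (seeded) synthetic corpus with full truth bookkeeping."""
    rng = np.random.default_rng((config.seed, 0x6E57))
    n = config.n_posts

    # audience classes
    if config.quota_classes:
        counts = _quota_counts(n, config.class_mix)
        classes = [i for i, c in enumerate(counts) for _ in range(c)]
        rng.shuffle(classes)
    else:
        classes = rng.choice(3, size=n, p=list(config.class_mix)).tolist()

    # sources
    src_names = list(config.source_mix.keys())
    src_p = np.array([config.source_mix[s] for s in src_names], dtype=float)
    src_p /= src_p.sum()
    sources = rng.choice(len(src_names), size=n, p=src_p)

    # symptom plant assignment: distinct posts, one plant each
    plant_slots: list[tuple[str, str]] = []
    for symptom, (neg, neu, pos) in config.symptom_plants.items():
        plant_slots += [(symptom, "negative")] * neg
        plant_slots += [(symptom, "neutral")] * neu
        plant_slots += [(symptom, "positive")] * pos
    plant_posts = rng.choice(n, size=len(plant_slots), replace=False)
    plant_for_post: dict[int, tuple[str, str]] = {
        int(i): slot for i, slot in zip(plant_posts, plant_slots)
    }

    all_cues = tuple(t for toks in CLASS_CUE_TOKENS.values() for t in toks)
    taxonomy = default_taxonomy()
    psy_pool = [
        (label, definition)
        for label in taxonomy.enabled_labels
        for definition in taxonomy[label]
    ]
    medsent_classes = ("recovery", "deteriorating", "condition_present")

    posts: list[SocialPost] = []
    truth: dict[str, PostTruth] = {}
    for i in range(n):
        audience = AUDIENCE_LABELS[classes[i]]
        source = src_names[int(sources[i])]
        parts: list[str] = []

        filler = rng.choice(len(_FILLER), size=int(rng.integers(4, 8)), replace=True)
        sent = " ".join(_FILLER[int(k)] for k in filler)
        parts.append(sent.capitalize() + ".")

        cues = []
        for _ in range(3):
            if rng.random() < config.signal_strength:
                pool = CLASS_CUE_TOKENS[audience]
            else:
                pool = all_cues
            cues.append(pool[int(rng.integers(len(pool)))])
        parts.append("Mostly " + " ".join(cues) + " here.")

        medsent_label: str | None = None
        medsent_agree: bool | None = None
        if rng.random() < config.medsent_rate:
            medsent_label = medsent_classes[
                int(rng.choice(3, p=list(config.medsent_mix)))
            ]
            medsent_agree = bool(rng.random() < config.medsent_agree_rate)
            if medsent_agree:
                parts.append(MEDSENT_AGREE_PHRASES[medsent_label])
            else:
                _, _, phrase = MEDSENT_DISAGREE_PHRASES[medsent_label]
                parts.append(phrase)

        # The symptom sentence precedes the psychosocial one: several
        # definitions end in negation cues ("... is not worthwhile") that
        # would otherwise fall inside the modifier window before the
        # symptom mention and flip its planted tonality.
        symptom = plant_for_post.get(i)
        if symptom is not None:
            parts.append(_TONALITY_TEMPLATES[symptom[1]].format(symptom=symptom[0]))

        psychosocial: tuple[str, str] | None = None
        if rng.random() < config.psychosocial_rate:
            label, definition = psy_pool[int(rng.integers(len(psy_pool)))]
            psychosocial = (label, definition)
            parts.append("Lately: " + definition + ".")

        pii_spans: list[tuple[int, int, str]] = []
        pii_token: str | None = None
        if rng.random() < config.pii_rate:
            pii_token = _PII_POOL[int(rng.integers(len(_PII_POOL)))]
            parts.append(f"Reach me at {pii_token} anytime.")

        handles: list[str] = []
        if source.is_twitter and rng.random() < config.mention_rate:
            k = int(rng.integers(1, 3))
            handles = [
                _MENTION_POOL[int(j)]
                for j in rng.choice(len(_MENTION_POOL), size=k, replace=False)
            ]
            parts.append(" ".join(handles) + " thanks.")

        text = " ".join(parts)
        if pii_token is not None:
            start = text.index(pii_token)
            pii_spans.append((start, start + len(pii_token), pii_token))

        post_id = f"synth-{config.seed}-{i:06d}"
        posts.append(
            SocialPost(
                post_id=post_id,
                text=text,
                source=source,
                sub_source=_SOURCE_SUB_SOURCES.get(source, ("unknown.site",))[
                    int(rng.integers(len(_SOURCE_SUB_SOURCES.get(source, ("x",)))))
                ],
                country=("US", "GB", "CA", "AU")[int(rng.integers(4))],
                date=f"2021-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}",
                indication=(
                    Indication.HEAD_AND_NECK if rng.random() < 0.5 else Indication.ESOPHAGEAL
                ),
            )
        )
        truth[post_id] = PostTruth(
            audience=audience,
            pii_spans=tuple(pii_spans),
            mention_handles=tuple(handles),
            symptom=symptom,
            medsent=medsent_label,
            medsent_agree=medsent_agree,
            psychosocial=psychosocial,
        )
    return SyntheticCorpus(posts=tuple(posts), truth=truth, config=config)


def generate_noisy_labels(
    corpus: SyntheticCorpus, alpha: float, seed: int
) -> list[LabeledExample]:
    """Audience labels from truth with label noise at rate alpha."""
    label_idx = {l: i for i, l in enumerate(AUDIENCE_LABELS)}
    clean = [
        LabeledExample(
            post=p,
            given_label=label_idx[corpus.truth[p.post_id].audience],
            true_label=label_idx[corpus.truth[p.post_id].audience],
        )
        for p in corpus.posts
    ]
    rng = np.random.default_rng((seed, 0xA1FA))
    return inject_noise(clean, alpha, rng, n_classes=len(AUDIENCE_LABELS))


# ---------------------------------------------------------------------------
# Mock backends

_TOKEN_RE = re.compile(r"[a-z0-9']+")

_STOPWORDS = frozenset(
    "a an the of in on at to is are was were that which it and or not no "
    "have has be being been by for with when after due about like you your "
    "up out seem able".split()
)


def _tokens(text: str) -> frozenset[str]:
    return frozenset(_TOKEN_RE.findall(text.lower()))


def _content_tokens(text: str) -> frozenset[str]:
    return frozenset(t for t in _tokens(text) if t not in _STOPWORDS)


def default_nli_cue_table() -> dict[str, frozenset[str]]:
    """Cue tokens per hypothesis: the two medical-sentiment hypothesis sets
    plus every built-in psychosocial definition (its content tokens)."""
    table: dict[str, frozenset[str]] = {}
    for label, hyp in HYPOTHESIS_SET_1.hypotheses:
        table[hyp] = _SET1_CUES[label]
    for label, hyp in HYPOTHESIS_SET_2.hypotheses:
        table[hyp] = _SET2_CUES[label]
    taxonomy = default_taxonomy()
    for label in taxonomy.enabled_labels:
        for definition in taxonomy[label]:
            table[definition] = _content_tokens(definition)
    return table


class MockNLIBackend:
    """Deterministic cue-overlap entailment scorer.

    For hypotheses in the cue table the score is a sharpened containment
    of the cue set in the premise: 0.05 + 0.9 * (hits/|cues|)^3, so a
    premise containing every cue token scores 0.95 and zero overlap
    scores 0.05; the cubic sharpening keeps partial lexical overlap from
    competing with a fully matched hypothesis.  Unknown hypotheses fall
    back to the (symmetric) Jaccard overlap of content-token sets on the
    same 0.05..0.95 scale.
    """

    def __init__(self, cue_table: Mapping[str, frozenset[str]] | None = None, seed: int = 0):
        self.cue_table = dict(cue_table) if cue_table is not None else default_nli_cue_table()
        if not self.cue_table:
            raise ValueError("cue_table must be non-empty")
        self.seed = seed  # reserved for stochastic variants; scoring is deterministic

    def score(self, premise: str, hypothesis: str) -> float:
        prem = _tokens(premise)
        cues = self.cue_table.get(hypothesis)
        if cues:
            frac = len(prem & cues) / len(cues)
            return 0.05 + 0.9 * frac**3
        a, b = _content_tokens(premise), _content_tokens(hypothesis)
        union = a | b
        j = len(a & b) / len(union) if union else 0.0
        return 0.05 + 0.9 * j


class MockSentimentBackend:
    """Deterministic lexicon-sum aspect sentiment: the polarity is the
    clamped sum of lexicon weights over the given text (the caller passes
    the aspect's sentence)."""

    def __init__(self, lexicon: Mapping[str, float] | None = None, seed: int = 0):
        self.lexicon = dict(lexicon) if lexicon is not None else dict(DEFAULT_SENTIMENT_LEXICON)
        self.seed = seed

    def polarity(self, text: str, aspect_span: tuple[int, int]) -> float:
        total = sum(
            self.lexicon.get(tok, 0.0) for tok in _TOKEN_RE.findall(text.lower())
        )
        return max(-1.0, min(1.0, total))


def mock_nli_backend(
    cue_table: Mapping[str, frozenset[str]] | None = None, seed: int = 0
) -> MockNLIBackend:
    return MockNLIBackend(cue_table, seed)


def mock_sentiment_backend(
    polarity_lexicon: Mapping[str, float] | None = None, seed: int = 0
) -> MockSentimentBackend:
    return MockSentimentBackend(polarity_lexicon, seed)
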