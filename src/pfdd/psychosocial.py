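"""Definition-anchored psychosocial-health labeling.

Posts from patients and caregivers are screened for five psychosocial
disorder labels — stress, depression, anxiety, panic, suicidal — using a
taxonomy of plain-language definition sentences per label (seeded from
the DASS-style screening items used to bootstrap the original model).
Each definition is scored as an NLI hypothesis against the post; the
winning definition supplies both the label and a machine-readable
*reason*, giving a two-level output (label + reason) that experts can
audit sentence by sentence.

No default definitions exist for *panic* and *suicidal*; those labels
ship disabled until a taxonomy file supplies them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import softmax

from .backends import BackendContractError, NLIBackend

__all__ = [
    "PSYCHOSOCIAL_LABELS",
    "DefinitionTaxonomy",
    "PsychosocialPrediction",
    "default_taxonomy",
    "load_taxonomy",
    "classify_psychosocial",
]

logger = logging.getLogger(__name__)

PSYCHOSOCIAL_LABELS: tuple[str, ...] = (
    "stress",
    "depression",
    "anxiety",
    "panic",
    "suicidal",
)

# Bootstrap screening definitions per label (DASS-style item phrasings).
_DEFAULT_DEFINITIONS: dict[str, list[str]] = {
    "depression": [
        "Not being able to experience positive feelings",
        "Could not seem to get going",
        "Feeling like you have nothing to look forward to",
        "Feeling lack of self-worth",
        "Feeling life is not worthwhile",
        "Not being able to find enjoyment",
        "Feeling downhearted and blue",
        "Unable to become enthusiastic about anything",
        "Feeling that life is meaningless",
        "Finding it difficult to work up the initiative to do things",
    ],
    "anxiety": [
        "Being aware of mouth dryness",
        "Experience breathing difficulties (breathlessness, excessive rapid "
        "breathing in the absence of physical exertion)",
        "Feeling of shakiness",
        "Relief when feelings that cause anxiousness end",
        "Feelings of faintness",
        "Sweating/perspiring in the absence of high temperature or physical exertion",
        "Feeling worried about situations in which one could panic and make a fool of myself",
        "Experience of trembling",
    ],
    "stress": [
        "Getting upset at trivial things",
        "Over-reacting to situations",
        "Finding it difficult to relax",
        "Getting upset rather easily",
        "Using a lot of nervous energy",
        "Getting impatient when delayed in any way in simple chores",
        "Feeling in a state of nervous tension",
        "Being intolerant of anything that keeps one from getting on with tasks at hand",
        "Getting agitated",
    ],
    "panic": [],
    "suicidal": [],
}


@dataclass(frozen=True)
class DefinitionTaxonomy:
    """Label -> ordered definition sentences; definitions unique across labels."""

    definitions: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, defs in self.definitions.items():
            if label not in PSYCHOSOCIAL_LABELS:
                raise ValueError(f"unknown psychosocial label: {label!r}")
            for d in defs:
                if not d.strip():
                    raise ValueError(f"{label}: empty definition")
                if d in seen:
                    raise ValueError(
                        f"definition {d!r} appears under both {seen[d]!r} and {label!r}"
                    )
                seen[d] = label

    @property
    def enabled_labels(self) -> tuple[str, ...]:
        return tuple(l for l in PSYCHOSOCIAL_LABELS if self.definitions.get(l))

    def __getitem__(self, label: str) -> tuple[str, ...]:
        return self.definitions[label]


@dataclass(frozen=True)
class PsychosocialPrediction:
    label: str | None
    reason: str | None  # the matched definition sentence
    score: float
    abstained: bool

    def to_record(self, post_id: str | None = None) -> dict:
        rec = {
            "label": self.label,
            "reason": self.reason,
            "score": self.score,
            "abstained": self.abstained,
        }
        if post_id is not None:
            rec = {"post_id": post_id, **rec}
        return rec


def default_taxonomy() -> DefinitionTaxonomy:
    return DefinitionTaxonomy(
        {label: tuple(defs) for label, defs in _DEFAULT_DEFINITIONS.items()}
    )


def load_taxonomy(path: str | Path | None = None, strict: bool = False) -> DefinitionTaxonomy:
    """Load a taxonomy from JSON/YAML, or the built-in default.

    ``strict=True`` requires every label to have at least one definition;
    otherwise empty labels are disabled with a logged notice.
    """
    if path is None:
        tax = default_taxonomy()
    else:
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: taxonomy must be a mapping label -> definitions")
        tax = DefinitionTaxonomy(
            {label: tuple(defs or ()) for label, defs in raw.items()}
        )
    empty = [l for l in tax.definitions if not tax.definitions[l]]
    if empty:
        if strict:
            raise ValueError(f"labels without definitions in strict mode: {', '.join(empty)}")
        logger.info("psychosocial labels disabled (no definitions): %s", ", ".join(empty))
    return tax


def classify_psychosocial(
    text: str,
    taxonomy: DefinitionTaxonomy,
    backend: NLIBackend,
    abstain_threshold: float = 0.5,
) -> PsychosocialPrediction:
    """Score every definition as a hypothesis against the post.

    Per-label aggregation is the max over that label's definitions (the
    reason must be a single sentence); the across-label score is the
    softmax of the per-label maxima.  Predictions scoring below
    ``abstain_threshold`` abstain.
    """
    if not 0.0 < abstain_threshold < 1.0:
        raise ValueError("abstain_threshold must lie in (0, 1)")
    labels = taxonomy.enabled_labels
    if not labels:
        raise ValueError("taxonomy has no enabled labels")

    best_scores = []
    best_defs = []
    for label in labels:
        scores = []
        for definition in taxonomy[label]:
            s = backend.score(text, definition)
            if not 0.0 <= s <= 1.0:
                raise BackendContractError(f"NLI score {s} outside [0, 1]")
            scores.append(s)
        k = int(np.argmax(scores))
        best_scores.append(scores[k])
        best_defs.append(taxonomy[label][k])

    probs = softmax(np.asarray(best_scores, dtype=float))
    winner = int(np.argmax(probs))
    score = float(probs[winner])
    if score < abstain_threshold:
        return PsychosocialPrediction(label=None, reason=None, score=score, abstained=True)
    return PsychosocialPrediction(
        label=labels[winner], reason=best_defs[winner], score=score, abstained=False
    )


def classify_many(
    texts: Sequence[str],
    taxonomy: DefinitionTaxonomy,
    backend: NLIBackend,
    abstain_threshold: float = 0.5,
) -> list[PsychosocialPrediction]:
    return [
        classify_psychosocial(t, taxonomy, backend, abstain_threshold) for t in texts
    ]
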