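"""Zero-shot medical-sentiment classification via NLI entailment consensus.

Treatment-experience texts are sorted into three classes — the patient is
*recovering*, *deteriorating*, or the *condition is still present* — with
no labeled training data.  Each text is the premise of an NLI task; each
class label is phrased as a hypothesis; softmax over the entailment scores
yields a class probability.  Because small changes in hypothesis wording
change the output, two independently-worded hypothesis sets are scored
and a prediction is accepted only when both sets agree, with the accepted
confidence being the mean of the two winning probabilities.  A confidence
threshold (0.90 by default) then keeps only high-quality predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import softmax

from .backends import BackendContractError, NLIBackend

__all__ = [
    "MEDSENT_LABELS",
    "HYPOTHESIS_SET_1",
    "HYPOTHESIS_SET_2",
    "HypothesisSet",
    "ZeroShotPrediction",
    "build_hypothesis",
    "zero_shot_classify",
    "consensus_classify",
    "filter_by_confidence",
    "evaluate_two_rater",
]

MEDSENT_LABELS: tuple[str, ...] = ("recovery", "deteriorating", "condition_present")


@dataclass(frozen=True)
class HypothesisSet:
    """Ordered (label, hypothesis) pairs; order breaks argmax ties."""

    set_id: int
    hypotheses: tuple[tuple[str, str], ...]  # (label, hypothesis text)

    def __post_init__(self) -> None:
        labels = [lbl for lbl, _ in self.hypotheses]
        if len(labels) != len(set(labels)):
            raise ValueError("each label must appear exactly once")
        if not labels:
            raise ValueError("hypothesis set must be non-empty")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.hypotheses)


HYPOTHESIS_SET_1 = HypothesisSet(
    set_id=1,
    hypotheses=(
        ("deteriorating", "health is deteriorating after treatment"),
        ("condition_present", "medical condition is still present"),
        ("recovery", "health is improving due to treatment"),
    ),
)

HYPOTHESIS_SET_2 = HypothesisSet(
    set_id=2,
    hypotheses=(
        ("deteriorating", "medical condition is deteriorating"),
        ("condition_present", "medical condition still exists"),
        ("recovery", "medical condition has subsided"),
    ),
)


@dataclass(frozen=True)
class ZeroShotPrediction:
    label: str | None
    probability: float | None
    set1_label: str
    set1_prob: float
    set2_label: str
    set2_prob: float
    accepted: bool

    def to_record(self, post_id: str | None = None) -> dict:
        rec = {
            "label": self.label,
            "probability": self.probability,
            "set1_label": self.set1_label,
            "set1_prob": self.set1_prob,
            "set2_label": self.set2_label,
            "set2_prob": self.set2_prob,
            "accepted": self.accepted,
        }
        if post_id is not None:
            rec = {"post_id": post_id, **rec}
        return rec


def build_hypothesis(label_text: str, template: str = "The text is about _____") -> str:
    """Substitute the label into a single-slot hypothesis template."""
    if not label_text:
        raise ValueError("label_text must be non-empty")
    slot = "_____"
    if template.count(slot) != 1:
        raise ValueError("template must contain exactly one '_____' slot")
    return template.replace(slot, label_text)


def zero_shot_classify(
    text: str, hset: HypothesisSet, backend: NLIBackend
) -> tuple[str, np.ndarray]:
    """Score every hypothesis, softmax the entailment scores, take the argmax.

    Ties break toward the first label in the set's declared order.
    Returns (winning label, probability simplex in set order).
    """
    scores = []
    for _, hypothesis in hset.hypotheses:
        s = backend.score(text, hypothesis)
        if not 0.0 <= s <= 1.0:
            raise BackendContractError(f"NLI score {s} outside [0, 1]")
        scores.append(s)
    probs = softmax(np.asarray(scores, dtype=float))
    winner = int(np.argmax(probs))  # argmax returns the first maximum
    return hset.labels[winner], probs


def consensus_classify(
    text: str,
    set1: HypothesisSet = HYPOTHESIS_SET_1,
    set2: HypothesisSet = HYPOTHESIS_SET_2,
    backend: NLIBackend | None = None,
) -> ZeroShotPrediction:
    """Accept a prediction only when both hypothesis sets agree.

    On agreement the confidence is the arithmetic mean of the two winning
    probabilities; on disagreement the prediction is rejected (kept in
    output with ``accepted=False`` for auditability).
    """
    if backend is None:
        raise ValueError("an NLI backend is required")
    if set(set1.labels) != set(set2.labels):
        raise ValueError("hypothesis sets must cover identical label vocabularies")
    label1, probs1 = zero_shot_classify(text, set1, backend)
    label2, probs2 = zero_shot_classify(text, set2, backend)
    p1 = float(probs1[set1.labels.index(label1)])
    p2 = float(probs2[set2.labels.index(label2)])
    if label1 == label2:
        return ZeroShotPrediction(
            label=label1,
            probability=(p1 + p2) / 2.0,
            set1_label=label1,
            set1_prob=p1,
            set2_label=label2,
            set2_prob=p2,
            accepted=True,
        )
    return ZeroShotPrediction(
        label=None,
        probability=None,
        set1_label=label1,
        set1_prob=p1,
        set2_label=label2,
        set2_prob=p2,
        accepted=False,
    )


def filter_by_confidence(
    preds: Sequence[ZeroShotPrediction], threshold: float = 0.90
) -> list[ZeroShotPrediction]:
    """Keep accepted predictions with probability >= threshold (inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return [p for p in preds if p.accepted and p.probability is not None and p.probability >= threshold]


def disagreement_rate(preds: Sequence[ZeroShotPrediction]) -> float:
    """Fraction of predictions where the two hypothesis sets disagree.

    Quantifies the sensitivity of zero-shot output to hypothesis wording.
    """
    if not preds:
        return 0.0
    return sum(1 for p in preds if p.set1_label != p.set2_label) / len(preds)


def evaluate_two_rater(
    predictions: Mapping[str, str],
    rater_a: Mapping[str, str],
    rater_b: Mapping[str, str],
) -> float:
    """Adjudicated accuracy: a prediction is correct iff both human raters
    agree with each other and with the prediction.

    All three mappings must cover the same post ids.
    """
    ids = set(predictions)
    if ids != set(rater_a) or ids != set(rater_b):
        raise ValueError("prediction and rater ids are misaligned")
    if not ids:
        raise ValueError("nothing to evaluate")
    correct = sum(
        1 for i in ids if rater_a[i] == rater_b[i] == predictions[i]
    )
    return correct / len(ids)
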