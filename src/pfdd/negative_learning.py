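"""Noise-robust audience classification via negative (complementary-label) learning.

Social-media audience labels (patient / caregiver / irrelevant) are cheap
but noisy.  Standard positive learning (PL) — cross-entropy on the given
label — overfits wrong labels.  Negative learning (NL) instead trains the
model *not* to predict a complementary label ȳ drawn uniformly from the
classes other than the given one:

    PL loss:  L(f, y)  = -sum_k y_k  log p_k          = -log p_y
    NL loss:  L(f, ȳ)  = -sum_k ȳ_k  log(1 - p_k)     = -log(1 - p_ȳ)

Because a randomly drawn complementary label is correct information with
probability at least as high as the given label, the posterior probability
of receiving true information under NL,

    P(True|NL) = p_y + 1/(n-1) * sum_{k != y} p_k  >=  p_y = P(True|PL),

never falls below positive learning's.  After NL training the model is
under-confident on mislabeled examples, so thresholding the predicted
probability of the given label separates clean from corrupted data.

Training follows a three-stage schedule: NL on all examples, then
selective NL restricted to high-confidence examples, then selective PL
(fine-tuning with cross-entropy) on the confidently-clean subset.
Complementary labels are either *fixed* (drawn once before training) or
*changed* (redrawn every epoch); in the changed regime resampling stops
once every example has seen all of its possible complementary labels,
since past that point fresh draws add no new information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score, precision_recall_fscore_support

from .backends import BagOfWordsSoftmaxBackend, ClassifierBackend, check_simplex
from .corpus import SocialPost

__all__ = [
    "AUDIENCE_LABELS",
    "LabeledExample",
    "NLConfig",
    "ConfidenceRecord",
    "EpochRecord",
    "EvalResult",
    "sample_complementary",
    "positive_loss",
    "negative_loss",
    "posterior_true_nl",
    "inject_noise",
    "assign_complementary",
    "train",
    "confidence_report",
    "separate_clean_noisy",
    "select_epoch",
    "evaluate",
    "stratified_split",
]

AUDIENCE_LABELS: tuple[str, ...] = ("patient", "caregiver", "irrelevant")

_EPS = 1e-12


@dataclass(frozen=True, slots=True)
class LabeledExample:
    """A post with a given (possibly noisy) label and simulation bookkeeping.

    ``corrupted`` and ``true_label`` exist only so simulations can audit
    themselves; training never reads them.
    """

    post: SocialPost
    given_label: int
    true_label: int | None = None
    corrupted: bool = False

    def __post_init__(self) -> None:
        if self.true_label is not None and self.corrupted != (
            self.given_label != self.true_label
        ):
            raise ValueError("corrupted flag inconsistent with labels")


@dataclass(frozen=True)
class NLConfig:
    """Training configuration.

    ``learning_rate=None`` defers to the backend's native default (the
    bag-of-words backend uses 1.0; a transformer adapter would use 1e-5).
    ``stage_epochs`` splits ``epochs`` across NL / selective-NL /
    selective-PL; when omitted the split is (half, quarter, rest).
    """

    n_classes: int = 3
    regime: str = "fixed"  # or "changed"
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float | None = None
    max_tokens: int = 512
    seed: int = 0
    stage_epochs: tuple[int, int, int] | None = None
    stage2_threshold: float | None = None  # default 1/n_classes
    stage3_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.regime not in ("fixed", "changed"):
            raise ValueError(f"unknown regime: {self.regime!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for t in (self.stage2_threshold, self.stage3_threshold):
            if t is not None and not (0.0 < t < 1.0):
                raise ValueError("confidence thresholds must lie in (0, 1)")

    def resolved_stage_epochs(self) -> tuple[int, int, int]:
        if self.stage_epochs is not None:
            return self.stage_epochs
        e1 = math.ceil(self.epochs / 2)
        e2 = self.epochs // 4
        return (e1, e2, self.epochs - e1 - e2)


@dataclass(frozen=True, slots=True)
class ConfidenceRecord:
    example_id: str
    probs: np.ndarray
    confidence: float  # probability of the given label
    predicted_label: int


@dataclass(frozen=True, slots=True)
class EpochRecord:
    epoch: int  # 1-based, over the whole run
    stage: int  # 1, 2 or 3
    loss: float
    n_selected: int
    accuracy_given: float  # agreement with given (possibly noisy) labels
    accuracy_clean: float | None  # vs true labels, clean partition
    accuracy_corrupted: float | None
    mean_conf_clean: float | None
    mean_conf_corrupted: float | None
    resampled: bool  # changed regime drew fresh complementary labels


@dataclass(frozen=True)
class EvalResult:
    accuracy: float
    macro_f1: float
    per_class_precision: tuple[float, ...]
    per_class_recall: tuple[float, ...]


# ---------------------------------------------------------------------------
# Loss primitives


def sample_complementary(given_label: int, n_classes: int, rng: np.random.Generator) -> int:
    """Draw ȳ uniformly from the classes other than the given one."""
    if n_classes < 2:
        raise ValueError("no complementary label exists for n_classes < 2")
    if not 0 <= given_label < n_classes:
        raise ValueError("given_label out of range")
    draw = int(rng.integers(n_classes - 1))
    return draw if draw < given_label else draw + 1


def positive_loss(p: Sequence[float], y: int) -> float:
    """Cross-entropy on the given label: -log p_y (floored at 1e-12)."""
    p = np.asarray(p, dtype=float)
    check_simplex(p)
    return float(-np.log(max(p[y], _EPS)))


def negative_loss(p: Sequence[float], y_bar: int) -> float:
    """Complementary-label loss: -log(1 - p_ȳ) (floored at 1e-12)."""
    p = np.asarray(p, dtype=float)
    check_simplex(p)
    return float(-np.log(max(1.0 - p[y_bar], _EPS)))


def posterior_true_nl(p: Sequence[float], y: int) -> float:
    """Posterior probability that a random complementary label is true info.

    p_y + 1/(n-1) * sum_{k != y} p_k; always >= p_y, with equality exactly
    when the off-label mass is zero.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[-1]
    if n < 2:
        raise ValueError("needs at least two classes")
    check_simplex(p)
    off = float(p.sum() - p[y])
    return float(p[y] + off / (n - 1))


# ---------------------------------------------------------------------------
# Noise simulation


def inject_noise(
    dataset: Sequence[LabeledExample], alpha: float, rng: np.random.Generator, n_classes: int = 3
) -> list[LabeledExample]:
    """Corrupt exactly round(alpha*N) labels (half-up), uniformly without replacement.

    Every example must start clean (given == true).  Corrupted examples
    get a uniform draw from the other classes and their flag set.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    for ex in dataset:
        if ex.corrupted or ex.true_label != ex.given_label:
            raise ValueError("inject_noise requires a clean dataset")
    n = len(dataset)
    k = int(math.floor(alpha * n + 0.5))
    out = list(dataset)
    for i in rng.choice(n, size=k, replace=False):
        ex = out[i]
        noisy = sample_complementary(ex.given_label, n_classes, rng)
        out[i] = replace(ex, given_label=noisy, corrupted=True)
    return out


def assign_complementary(
    given_labels: Sequence[int],
    n_classes: int,
    regime: str,
    epoch: int,
    seed: int,
) -> np.ndarray:
    """Complementary label per example for one epoch.

    fixed: the draw depends on the seed only, so every epoch gets the same
    assignment.  changed: the draw is re-seeded per epoch.  Assignments
    never equal the given label.
    """
    if regime == "fixed":
        rng = np.random.default_rng((seed, 0x5EED))
    elif regime == "changed":
        rng = np.random.default_rng((seed, 0x5EED, epoch))
    else:
        raise ValueError(f"unknown regime: {regime!r}")
    y = np.asarray(given_labels, dtype=int)
    draw = rng.integers(n_classes - 1, size=len(y))
    return np.where(draw < y, draw, draw + 1)


# ---------------------------------------------------------------------------
# Training


def _partition_stats(
    probs: np.ndarray, dataset: Sequence[LabeledExample]
) -> tuple[float, float | None, float | None, float | None, float | None]:
    given = np.array([ex.given_label for ex in dataset])
    pred = probs.argmax(axis=1)
    conf = probs[np.arange(len(dataset)), given]
    acc_given = float((pred == given).mean())

    flags = np.array([ex.corrupted for ex in dataset])
    truth_known = all(ex.true_label is not None for ex in dataset)
    if not truth_known:
        return acc_given, None, None, None, None
    true = np.array([ex.true_label for ex in dataset])
    acc_clean = float((pred[~flags] == true[~flags]).mean()) if (~flags).any() else None
    acc_corr = float((pred[flags] == true[flags]).mean()) if flags.any() else None
    conf_clean = float(conf[~flags].mean()) if (~flags).any() else None
    conf_corr = float(conf[flags].mean()) if flags.any() else None
    return acc_given, acc_clean, acc_corr, conf_clean, conf_corr


def _balanced_selection(
    conf: np.ndarray, given: np.ndarray, n_classes: int, threshold: float
) -> np.ndarray:
    """Class-balanced confident subset for the selective stages.

    Per given-label class, take the examples at or above the confidence
    threshold, ranked by confidence; every class is truncated to the size
    of the smallest class's above-threshold pool so positive learning on
    the subset cannot collapse onto one over-represented class.  A class
    with nothing above threshold contributes its most-confident examples
    up to the same quota.
    """
    per_class = []
    for c in range(n_classes):
        idx = np.flatnonzero(given == c)
        idx = idx[np.argsort(-conf[idx], kind="stable")]
        per_class.append(idx)
    counts = [int((conf[idx] >= threshold).sum()) for idx in per_class]
    k = min(counts)
    if k == 0:
        positive = [c for c in counts if c > 0]
        k = min(positive) if positive else 0
    if k == 0:
        return np.array([], dtype=int)
    out = np.concatenate([idx[:k] for idx in per_class if idx.size])
    return out


def train(
    noisy_set: Sequence[LabeledExample],
    config: NLConfig,
    backend: ClassifierBackend | None = None,
) -> tuple[ClassifierBackend, list[EpochRecord]]:
    """Three-stage negative-learning run.

    Stage 1: NL on every example, complementary labels per regime.
    Stage 2: NL restricted, each epoch, to examples whose confidence
    (probability of the given label) is at least ``stage2_threshold``
    (default 1/n).  Stage 3: PL on examples above ``stage3_threshold``.
    Returns the trained backend and the per-epoch history.
    """
    if not noisy_set:
        raise ValueError("empty training set")
    n = config.n_classes
    if backend is None:
        kwargs = {} if config.learning_rate is None else {"learning_rate": config.learning_rate}
        backend = BagOfWordsSoftmaxBackend(
            n_classes=n, max_tokens=config.max_tokens, seed=config.seed, **kwargs
        )

    texts = [ex.post.text for ex in noisy_set]
    given = np.array([ex.given_label for ex in noisy_set])
    if given.min() < 0 or given.max() >= n:
        raise ValueError("labels out of range for n_classes")
    N = len(noisy_set)
    rng = np.random.default_rng((config.seed, 0xBA7C4))

    # changed-regime guard: once every example has seen all its n-1
    # complementary labels, further resampling is frozen.
    coverage = [set() for _ in range(N)]
    covered = False
    last_assignment: np.ndarray | None = None

    history: list[EpochRecord] = []
    stage_epochs = config.resolved_stage_epochs()
    thr2 = config.stage2_threshold if config.stage2_threshold is not None else 1.0 / n
    thr3 = config.stage3_threshold

    epoch = 0
    for stage, n_epochs in zip((1, 2, 3), stage_epochs):
        for _ in range(n_epochs):
            epoch += 1
            mode = "positive" if stage == 3 else "negative"

            # per-epoch selection for the selective stages
            if stage == 1:
                selected = np.arange(N)
            else:
                probs = backend.predict_proba(texts)
                check_simplex(probs)
                conf = probs[np.arange(N), given]
                thr = thr2 if stage == 2 else thr3
                selected = _balanced_selection(conf, given, n, thr)
                if selected.size == 0:
                    history.append(
                        EpochRecord(epoch, stage, float("nan"), 0,
                                    *_partition_stats(probs, noisy_set), resampled=False)
                    )
                    continue

            resampled = False
            if mode == "negative":
                if config.regime == "changed" and covered:
                    assignment = last_assignment
                else:
                    assignment = assign_complementary(
                        given, n, config.regime, epoch, config.seed
                    )
                    resampled = config.regime == "changed"
                    last_assignment = assignment
                    if config.regime == "changed" and not covered:
                        for i, c in enumerate(assignment):
                            coverage[i].add(int(c))
                        covered = all(len(s) == n - 1 for s in coverage)
                targets = assignment
            else:
                targets = given

            order = selected[rng.permutation(selected.size)]
            losses = []
            for start in range(0, order.size, config.batch_size):
                batch = order[start : start + config.batch_size]
                losses.append(
                    backend.fit_step(
                        [texts[i] for i in batch], targets[batch].tolist(), mode
                    )
                )
            probs = backend.predict_proba(texts)
            check_simplex(probs)
            history.append(
                EpochRecord(
                    epoch,
                    stage,
                    float(np.mean(losses)) if losses else float("nan"),
                    int(order.size),
                    *_partition_stats(probs, noisy_set),
                    resampled=resampled,
                )
            )
    return backend, history


def confidence_report(
    backend: ClassifierBackend, dataset: Sequence[LabeledExample]
) -> list[ConfidenceRecord]:
    """Per-example confidence = predicted probability of the given label."""
    texts = [ex.post.text for ex in dataset]
    probs = backend.predict_proba(texts)
    check_simplex(probs)
    return [
        ConfidenceRecord(
            example_id=ex.post.post_id,
            probs=probs[i],
            confidence=float(probs[i, ex.given_label]),
            predicted_label=int(probs[i].argmax()),
        )
        for i, ex in enumerate(dataset)
    ]


def separate_clean_noisy(
    records: Sequence[ConfidenceRecord], threshold: float
) -> tuple[list[str], list[str]]:
    """Partition example ids into clean (confidence >= threshold) and noisy."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    clean = [r.example_id for r in records if r.confidence >= threshold]
    noisy = [r.example_id for r in records if r.confidence < threshold]
    return clean, noisy


def select_epoch(
    history: Sequence[EpochRecord] | Sequence[float], inherent_accuracy: float
) -> int:
    """Epoch (1-based) whose training accuracy is closest to the dataset's
    inherent accuracy; ties go to the earlier epoch."""
    if not history:
        raise ValueError("empty history")
    if not 0.0 < inherent_accuracy <= 1.0:
        raise ValueError("inherent_accuracy must lie in (0, 1]")
    accs = [
        h.accuracy_given if isinstance(h, EpochRecord) else float(h) for h in history
    ]
    best = min(range(len(accs)), key=lambda i: (abs(accs[i] - inherent_accuracy), i))
    return best + 1


def evaluate(backend: ClassifierBackend, test_set: Sequence[LabeledExample]) -> EvalResult:
    """Accuracy and macro F1 (undefined classes score 0) on a clean test set."""
    if not test_set:
        raise ValueError("empty test set")
    texts = [ex.post.text for ex in test_set]
    y_true = [ex.given_label for ex in test_set]
    y_pred = backend.predict_proba(texts).argmax(axis=1)
    labels = list(range(backend.n_classes))
    prec, rec, _, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    return EvalResult(
        accuracy=float(np.mean(np.asarray(y_true) == y_pred)),
        macro_f1=float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        per_class_precision=tuple(float(x) for x in prec),
        per_class_recall=tuple(float(x) for x in rec),
    )


def stratified_split(
    dataset: Sequence[LabeledExample], test_frac: float = 0.1, seed: int = 0
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Seeded stratified train/test split (default 90/10) by given label."""
    rng = np.random.default_rng((seed, 0x51717))
    by_class: dict[int, list[int]] = {}
    for i, ex in enumerate(dataset):
        by_class.setdefault(ex.given_label, []).append(i)
    test_idx: set[int] = set()
    for idxs in by_class.values():
        idxs = np.array(idxs)
        k = int(round(test_frac * len(idxs)))
        test_idx.update(rng.choice(idxs, size=k, replace=False).tolist())
    train_set = [ex for i, ex in enumerate(dataset) if i not in test_idx]
    test_set = [ex for i, ex in enumerate(dataset) if i in test_idx]
    return train_set, test_set
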