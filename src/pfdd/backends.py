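"""Pluggable model backends.

Three contracts keep the heavy models swappable:

* :class:`ClassifierBackend` — multi-class text classifier trainable one
  optimization step at a time with either a positive (cross-entropy on the
  given label) or negative (complementary-label) loss.  The shipped
  default is a hashed bag-of-words linear softmax model trained by SGD,
  fast enough for desk-scale simulation; a transformer encoder can be
  adapted behind the same surface.
* :class:`NLIBackend` — scores entailment of a hypothesis by a premise in
  [0, 1]; used by the zero-shot medical-sentiment and psychosocial stages.
* :class:`SentimentBackend` — aspect-conditioned polarity in [-1, 1];
  used by symptom-severity scoring.

Deterministic mock NLI/sentiment backends live in :mod:`pfdd.synth`.
"""

from __future__ import annotations

import json
import re
import zlib
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "ClassifierBackend",
    "NLIBackend",
    "SentimentBackend",
    "BackendContractError",
    "BagOfWordsSoftmaxBackend",
    "check_simplex",
]

_EPS = 1e-12


class BackendContractError(RuntimeError):
    """A backend violated its numeric contract (simplex / range)."""


@runtime_checkable
class ClassifierBackend(Protocol):
    n_classes: int

    def fit_step(
        self, texts: Sequence[str], labels: Sequence[int], loss_mode: str
    ) -> float:
        """One optimization step; ``loss_mode`` is 'positive' or 'negative'.

        ``labels`` are given labels (positive mode) or complementary
        labels (negative mode).  Returns the mean batch loss.
        """
        ...

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        """(n_texts, n_classes) array of probability simplexes."""
        ...


@runtime_checkable
class NLIBackend(Protocol):
    def score(self, premise: str, hypothesis: str) -> float:
        """Entailment score in [0, 1]; deterministic for fixed inputs."""
        ...


@runtime_checkable
class SentimentBackend(Protocol):
    def polarity(self, text: str, aspect_span: tuple[int, int]) -> float:
        """Aspect-conditioned polarity in [-1, 1]."""
        ...


def check_simplex(p: np.ndarray, atol: float = 1e-6) -> None:
    p = np.asarray(p)
    if np.any(p < -atol) or np.any(np.abs(p.sum(axis=-1) - 1.0) > atol):
        raise BackendContractError("predicted probabilities are not a valid simplex")


_TOKEN_RE = re.compile(r"[a-z0-9']+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


class BagOfWordsSoftmaxBackend:
    """Hashed bag-of-words features + single softmax layer trained by SGD.

    Tokens hash (CRC-32, process-independent) into ``n_features`` buckets;
    the feature vector is L2-normalized term presence.  Both loss modes
    share the softmax output p = softmax(xW + b):

    * positive: L = -log p_y, gradient dL/dz = p - onehot(y)
    * negative: L = -log(1 - p_ybar),
      gradient dL/dz_k = p_ybar * (1[k = ybar] - p_k) / (1 - p_ybar)

    Probabilities are floored at 1e-12 inside the logs so losses stay
    finite.
    """

    STATE_VERSION = 1

    def __init__(
        self,
        n_classes: int,
        n_features: int = 4096,
        learning_rate: float = 1.0,
        max_tokens: int = 512,
        seed: int = 0,
    ) -> None:
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_classes = n_classes
        self.n_features = n_features
        self.learning_rate = learning_rate
        self.max_tokens = max_tokens
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0.0, 1e-3, size=(n_features, n_classes))
        self.b = np.zeros(n_classes)
        self._cache: dict[str, np.ndarray] = {}

    # -- features ----------------------------------------------------------
    def _vector(self, text: str) -> np.ndarray:
        v = self._cache.get(text)
        if v is not None:
            return v
        idx = {
            zlib.crc32(tok.encode("utf-8")) % self.n_features
            for tok in _tokenize(text)[: self.max_tokens]
        }
        v = np.zeros(self.n_features)
        if idx:
            v[list(idx)] = 1.0 / np.sqrt(len(idx))
        if len(self._cache) < 200_000:
            self._cache[text] = v
        return v

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self._vector(t) for t in texts])

    # -- inference ---------------------------------------------------------
    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        X = self.encode(texts)
        z = X @ self.W + self.b
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- training ----------------------------------------------------------
    def fit_step(
        self, texts: Sequence[str], labels: Sequence[int], loss_mode: str
    ) -> float:
        if loss_mode not in ("positive", "negative"):
            raise ValueError(f"unknown loss_mode: {loss_mode!r}")
        X = self.encode(texts)
        y = np.asarray(labels, dtype=int)
        n = len(y)
        z = X @ self.W + self.b
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        rows = np.arange(n)
        if loss_mode == "positive":
            loss = float(np.mean(-np.log(np.maximum(p[rows, y], _EPS))))
            g = p.copy()
            g[rows, y] -= 1.0
        else:
            p_bar = p[rows, y]
            loss = float(np.mean(-np.log(np.maximum(1.0 - p_bar, _EPS))))
            onehot = np.zeros_like(p)
            onehot[rows, y] = 1.0
            scale = (p_bar / np.maximum(1.0 - p_bar, _EPS))[:, None]
            g = scale * (onehot - p)
        g /= n
        self.W -= self.learning_rate * (X.T @ g)
        self.b -= self.learning_rate * g.sum(axis=0)
        return loss

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "version": self.STATE_VERSION,
            "n_classes": self.n_classes,
            "n_features": self.n_features,
            "learning_rate": self.learning_rate,
            "max_tokens": self.max_tokens,
        }
        np.savez(path, W=self.W, b=self.b, meta=json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "BagOfWordsSoftmaxBackend":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["version"] != cls.STATE_VERSION:
                raise ValueError(f"unsupported model state version {meta['version']}")
            obj = cls(
                n_classes=meta["n_classes"],
                n_features=meta["n_features"],
                learning_rate=meta["learning_rate"],
                max_tokens=meta["max_tokens"],
            )
            obj.W = data["W"].copy()
            obj.b = data["b"].copy()
        return obj
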