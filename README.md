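# pfdd — patient-experience mining from social media

`pfdd` is a research pipeline for extracting patient-experience insights
from public social-media posts to support patient-focused drug
development. It covers the full listening flow: corpus cleaning,
noise-robust audience classification via **negative learning**, zero-shot
medical-sentiment classification via **NLI hypothesis consensus**,
definition-anchored psychosocial labeling, and aspect-based
symptom-severity scoring — plus a seeded synthetic-corpus generator and
deterministic mock backends so every stage runs offline on a CPU in
seconds.

## The scientific problem

Social-media posts about a disease are abundant but messy: audience
labels (is the author a patient, a caregiver, or neither?) are cheap to
collect and highly noisy, and the concepts of interest (treatment
sentiment, psychosocial burden, symptom severity) have no labeled
training data at all. The package implements three model families to
work under those constraints.

### Negative learning for noisy labels

Standard positive learning (PL) minimizes cross-entropy on the given
label and overfits wrong labels. Negative learning (NL) instead draws a
*complementary* label ȳ uniformly from the classes other than the given
one and trains the model **not** to predict it:

```
PL:  L(f, y) = −log p_y
NL:  L(f, ȳ) = −log(1 − p_ȳ)
```

A random complementary label is correct information with probability at
least that of the given label; the posterior probability of receiving
true information under NL,

```
P(True | NL) = p_y + (1 / (n−1)) · Σ_{k≠y} p_k  ≥  p_y = P(True | PL),
```

is never inferior to PL's (`posterior_true_nl` asserts this as a
property). Training runs in three stages — NL on everything, selective
NL on confident examples (confidence ≥ 1/n), then selective PL
fine-tuning (confidence ≥ 0.5) — with complementary labels either
*fixed* (drawn once) or *changed* (redrawn per epoch). After NL training
the predicted probability of the given label cleanly separates clean
from mislabeled examples.

### Zero-shot classification by NLI consensus

Each post is the premise of a natural-language-inference task and each
class is phrased as a hypothesis; softmax over the entailment scores
gives class probabilities. Because zero-shot output is sensitive to
hypothesis wording, two independently worded hypothesis sets are scored
and a prediction is accepted only when both agree, with confidence the
mean of the two winning probabilities. The same machinery, pointed at a
taxonomy of screening-item definitions, yields psychosocial labels with
a per-post *reason* (the winning definition sentence).

### Aspect-based symptom severity

Symptom phrases from a clinical taxonomy are matched in posts; each
mention's tonality is the sentiment of its containing sentence, adjusted
by modifier rules (negation flips sign, degree words scale, slang and
emoticons add signed increments) and discretized with a ±0.05 dead zone.
A symptom's **severity** is the number of distinct posts discussing it
in negative tonality.

## Worked example

```python
import numpy as np
from sklearn.metrics import roc_auc_score

import pfdd.negative_learning as nl
from pfdd.synth import GeneratorConfig, MockNLIBackend, generate_corpus, generate_noisy_labels
from pfdd.medsent import consensus_classify

# 1,000 synthetic posts, 30% of the audience labels corrupted
corpus = generate_corpus(GeneratorConfig(n_posts=1000, seed=7))
examples = generate_noisy_labels(corpus, alpha=0.3, seed=7)

train_set, test_set = nl.stratified_split(examples, test_frac=0.1, seed=7)
backend, history = nl.train(train_set, nl.NLConfig(regime="changed", epochs=20, seed=7))

clean_test = [ex for ex in test_set if not ex.corrupted]
result = nl.evaluate(backend, clean_test)
print(f"held-out accuracy on clean labels: {result.accuracy:.3f}")
print(f"held-out macro F1:                 {result.macro_f1:.3f}")

records = nl.confidence_report(backend, train_set)
auc = roc_auc_score([not ex.corrupted for ex in train_set],
                    [r.confidence for r in records])
print(f"clean-vs-corrupted confidence AUC: {auc:.3f}")

pred = consensus_classify(
    "Things got worse and keep declining, the treatment is failing "
    "and everything is deteriorating.",
    backend=MockNLIBackend(),
)
print(f"consensus sentiment: {pred.label} (p={pred.probability:.3f})")
```

Output (deterministic for the seeds shown):

```
held-out accuracy on clean labels: 0.913
held-out macro F1:                 0.915
clean-vs-corrupted confidence AUC: 0.978
consensus sentiment: deteriorating (p=0.552)
```

Despite 30% of the training labels being wrong, the negative-learning
classifier recovers 91% accuracy on clean held-out labels, and its
confidence ranks corrupted examples far below clean ones (AUC 0.978).

## Command line

```bash
pfdd synth --n 1000 --seed 7 --out corpus.jsonl --truth truth.jsonl
pfdd preprocess --input corpus.jsonl --out clean.jsonl --block-source print_news
pfdd nl-train --n 1000 --alpha 0.3 --regime changed --seed 7 --model-out model.npz
pfdd classify --input clean.jsonl --model model.npz --out audience.jsonl
pfdd nl-sweep --alphas 20,30,40,50,60,70 --seed 7 --out sweep.csv
pfdd medsent --input clean.jsonl --out medsent.jsonl
pfdd psychosocial --input clean.jsonl --out psychosocial.jsonl
pfdd severity --input clean.jsonl --out severity.csv
pfdd run --seed 5 --out pipeline_out
pfdd report --insights pipeline_out/insights.jsonl --out pipeline_out/summary
```

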