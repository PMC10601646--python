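# Methods

This note documents the models, the parameter defaults and why they are
what they are, the numerical choices, and the scope and limits of the
simulation stack.

## 1. Corpus model and preprocessing

A corpus is a flat list of `SocialPost` records (`post_id`, `text`,
`source`, `sub_source`, `country`, `date`, `indication`) read from CSV
or JSONL. Cleaning applies five steps in a fixed order:

1. **Source filter** — drop blocked source types (e.g. print news,
   podcast messages, which are rarely first-person experience).
2. **Keyword query** — boolean include/exclude phrase query,
   case-insensitive, whole-phrase on word boundaries; exclusion
   dominates inclusion.
3. **PII scrub** — emails, phone-like digit runs (7–15 digits with
   separators), US ZIP / UK postcodes, and an optional name gazetteer
   are replaced by the literal `[PII]`. The placeholder contains no
   digits or `@`, so scrubbing is idempotent.
4. **Sub-source filter** — drop blocked sites.
5. **Mention strip** — remove `@handle` tokens from twitter-sourced
   posts only (an `@` inside an email is the scrubber's job, protected
   by a lookbehind).

Posts whose text becomes empty are dropped and counted. Every run emits
a `PreprocessReport` whose `validate()` asserts the conservation law
`output == input − drops`.

## 2. Negative learning

### Losses and posterior

For a probability simplex `p` over `n` classes:

- positive (PL) loss: `−log p_y`
- negative (NL) loss on complementary label ȳ: `−log(1 − p_ȳ)`
- posterior probability that a uniformly drawn complementary label is
  true information: `p_y + (1/(n−1))·Σ_{k≠y} p_k ≥ p_y`, with equality
  exactly when the off-label mass is zero.

Probabilities are floored at `1e-12` inside logarithms so losses remain
finite at the simplex boundary.

### Three-stage schedule

- **Stage 1 (NL)**: complementary-label training on every example.
- **Stage 2 (selective NL)**: each epoch, restricted to examples whose
  confidence (predicted probability of the *given* label) is at least
  `1/n`.
- **Stage 3 (selective PL)**: cross-entropy fine-tuning on examples with
  confidence ≥ 0.5.

The default split of `epochs` across stages is (half, quarter, rest);
with the default 20 epochs that is (10, 5, 5).

**Class-balanced selection.** In the selective stages the confident
subset is balanced by given-label class: each class contributes its
most-confident examples, truncated to the size of the smallest class's
above-threshold pool (a class with nothing above threshold contributes
its top examples up to the same quota). Without this, at high noise
rates the confident pool is dominated by one class and stage-3 positive
learning collapses onto it. This is a design choice of this package, an
addition to the standard three-stage recipe.

### Complementary-label regimes

- **fixed** — ȳ is drawn once per example before training.
- **changed** — ȳ is redrawn every epoch; once every example has seen
  all of its `n−1` possible complementary labels, resampling is frozen
  (further draws add no information).

### Noise simulation

`inject_noise` corrupts exactly `round(αN)` labels (half-up rounding),
chosen uniformly without replacement; a corrupted label is a uniform
draw from the other classes and is never equal to the original.
`LabeledExample` carries `true_label`/`corrupted` for audit only —
training never reads them.

### Epoch selection and evaluation

`select_epoch` returns the 1-based epoch whose training accuracy is
closest to the dataset's *inherent accuracy* (the estimated fraction of
correct given-labels), breaking ties toward the earlier epoch.
Evaluation reports accuracy and macro F1 (scikit-learn, `zero_division=0`).

### Backend and defaults

The shipped classifier is a hashed bag-of-words linear softmax model:
CRC-32 token hashing into 4,096 buckets (process-independent, unlike
Python's salted `hash`), L2-normalized presence vectors, SGD on the
exact gradients of both losses:

- positive: `dL/dz = p − onehot(y)`
- negative: `dL/dz_k = p_ȳ (1[k=ȳ] − p_k) / (1 − p_ȳ)`

Defaults: `epochs=20`, `batch_size=16`, `max_tokens=512`,
`learning_rate=None` meaning the backend's native default. The
bag-of-words backend uses **learning rate 1.0** — appropriate for a
single linear layer over sparse normalized features, and chosen (with
the balanced selection above) so the three-stage schedule remains stable
at 50–60% label noise. A transformer adapter behind the same
`ClassifierBackend` protocol would use its own conventional rate
(~1e-5); that rate would be a no-op for the linear model, which is why
the package treats the learning rate as a backend property rather than a
pipeline constant.

## 3. Zero-shot medical sentiment

Classes: `recovery`, `deteriorating`, `condition_present`. Each class is
phrased as an NLI hypothesis; the premise is the post. Scores in [0, 1]
are softmaxed and the argmax wins (ties break toward the declared
hypothesis order). Two independently worded hypothesis sets are scored;
a prediction is **accepted only when both agree**, with confidence the
arithmetic mean of the two winning probabilities. Rejected predictions
are kept in outputs with `accepted=false` for auditability.
`filter_by_confidence` uses an inclusive boundary (`p ≥ threshold`).

Two-rater evaluation: a prediction is correct iff both human raters
agree with each other *and* with the prediction; accuracy is the count
of such posts over all evaluated posts.

**Threshold note.** The conventional confidence threshold is 0.90 under
a real NLI model whose entailment scores are logits. The mock backend's
scores live in [0, 1]; a softmax over three such scores is bounded near
`e^1/(e^1+2e^0) ≈ 0.576`, so the end-to-end pipeline defaults to a 0.5
threshold when running on mocks. The 0.90 boundary semantics are tested
directly on constructed probabilities.

## 4. Psychosocial labeling

Labels: stress, depression, anxiety, panic, suicidal. Each label owns a
list of plain-language definition sentences (DASS-style screening
items); every definition is scored as an NLI hypothesis against the
post. Per-label aggregation is the **max** over that label's definitions
(the reason must be one sentence); the across-label distribution is the
softmax of the per-label maxima; predictions below the abstain threshold
(default 0.5) abstain. The winning definition is returned as the
machine-readable *reason*. No built-in definitions exist for *panic*
and *suicidal*; those labels ship disabled until a taxonomy file
supplies them (strict loading mode turns that into an error).

## 5. Symptom severity

A fixed taxonomy of 20 head & neck / esophageal presentation phrases
(plus optional synonyms) is matched case-insensitively on word
boundaries; overlapping matches resolve longest-first. A mention's base
polarity is the sentiment of its containing sentence (naive
punctuation-based sentence splitting), conditioned on the aspect span.
Modifier rules apply in a fixed order within a 5-token window on either
side of the mention:

1. negation cues flip the sign (odd count flips, even cancels),
2. degree words scale magnitude (comparative ×1.25, superlative ×1.5),
3. slang terms add signed increments,
4. emoticons add signed increments (matched against raw tokens, since
   punctuation is the signal),

then the result is clamped to [−1, 1] and discretized with a dead zone:
negative below −0.05, positive above +0.05, neutral between. Severity is
the number of **distinct posts** with at least one negative mention of
the symptom; ranking is severity-descending with ties by name.

## 6. Synthetic corpus generator

`generate_corpus` is fully seeded and emits per-post ground truth
(audience class, PII spans with exact offsets, planted mentions, one
planted symptom sentence with known tonality, planted medical-sentiment
phrases, planted psychosocial definitions). Design points:

- **Controlled vocabulary.** All token pools (filler, class cues,
  sentiment words, templates) are mutually disjoint and avoid every
  modifier-lexicon word, so planted tonality survives the modifier rules
  and cue-overlap arithmetic is exact.
- **Part order.** The symptom sentence precedes the psychosocial
  sentence because several definitions end in negation cues ("… is not
  worthwhile") that would otherwise fall inside the modifier window
  before the mention and flip its planted tonality.
- **Class mixing.** `signal_strength` is the class-conditional cue rate:
  each post carries three cue slots, each drawn from its own class's
  vocabulary with probability `s` and from the pooled vocabulary
  otherwise; 0 gives chance-level separability, 1 near-separability.
  Class counts use largest-remainder quotas by default so composition is
  exact.
- **Planted disagreement.** Medical-sentiment phrases come in an
  "agree" flavor (cues for both hypothesis sets of one class) and a
  "disagree" flavor (set-1 cues of one class mixed with set-2 cues of
  another), so consensus acceptance and rejection are both exercised
  with known ground truth.

### Mock backends

- **NLI**: for hypotheses in its cue table the score is a sharpened
  containment `0.05 + 0.9·(hits/|cues|)³` (full match 0.95, no overlap
  0.05; the cube keeps partial lexical overlap from competing with a
  fully matched hypothesis). Unknown hypotheses fall back to Jaccard
  overlap of content tokens on the same scale.
- **Sentiment**: clamped sum of lexicon weights over the given sentence.

Both are deterministic, honor the same numeric contracts as real
transformer backends (`check_simplex`, score/polarity ranges), and are
**not** models of language — they exist so that planted-signal recovery
is exactly decidable.

## 7. Pipeline and determinism

`run_pipeline` executes: input (file or synthetic) → five-step cleaning
→ audience training + gating (posts predicted *irrelevant* never reach
the extractors) → medical sentiment, psychosocial, severity →
`insights.jsonl` (sorted JSON keys), `run_report.json` (per-stage
counts), `severity.csv`. One integer seed drives every stochastic
stage; all derived RNG streams use distinct fixed salt constants, so
identical configuration and inputs give byte-identical outputs.
`export_report` emits flat audience / sentiment / psychosocial /
severity count tables in CSV or JSONL (header-only when empty).

## 8. Numerical choices

- Probabilities validated as simplexes to `1e-6` absolute tolerance;
  contract violations raise `BackendContractError` rather than
  propagating NaNs.
- Log arguments floored at `1e-12`.
- Softmax via `scipy.special.softmax` (max-shifted, overflow-safe).
- `round(αN)` uses `floor(αN + 0.5)` — deterministic half-up, not
  banker's rounding.
- CRC-32 hashing makes the feature map identical across processes and
  platforms.

## 9. Limitations

- The mock NLI/sentiment backends are lexical; headline accuracies from
  large-corpus transformer studies are out of scope and not claimed.
  The tests assert arithmetic oracles and qualitative behavior
  (confidence separation, noise-robustness trends, planted-signal
  recovery, determinism) instead.
- The consensus confidence cap under mock scores (≈0.576 for 3 classes)
  means the 0.90 operating threshold is exercised on constructed
  probabilities, not end-to-end through mocks.
- Sentence splitting is naive punctuation-based; abbreviation-heavy text
  will mis-scope aspect sentiment.
- PII scrubbing is pattern-based (emails, digit runs, postcodes, a name
  gazetteer); free-text names outside the gazetteer are not detected.
- The bag-of-words classifier ignores word order; it is a fast stand-in
  whose purpose is to make the negative-learning machinery testable, not
  a competitive text classifier.
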