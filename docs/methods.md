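# Methods

## Problem and model

`igfuse` detects suicidal ideation in short social-media posts
(microblogs) as a binary text-classification problem: given a cleaned,
tokenized post, estimate P(y = 1 | text), where y = 1 marks text
indicative of suicidal ideation.

The classifier is a dual-channel network whose two encoders look at the
same embedded token sequence from complementary angles:

1. **Embedding.** Each token index is mapped to a d-dimensional vector
   as the sum of three learned tables — token, segment and position
   embeddings (the Transformer input convention). Posts are single
   sentences, so the segment id is constant 0; the table is retained for
   interface compatibility with contextual encoders. A pretrained
   contextual encoder can be registered behind the same contract
   (`"bert-adapter"`); the package ships no weights, and requesting the
   adapter without a registered backend is an explicit capability error.
2. **Local channel (multi-kernel CNN).** Parallel valid convolutions
   with kernel sizes (5, 7, 3) — the top three of the empirical priority
   order (5, 7, 3, 6, 4, 2) over window sizes 2–7, three sizes being the
   count at which performance peaks before overfitting — each with 128
   filters, ReLU, per-filter max-pooling over time, concatenated into
   the local feature vector x.
3. **Context channel (BiLSTM).** One standard LSTM per direction
   (independent parameters, zero initial states, 128 units each); the
   channel output at timestep t concatenates the forward and backward
   hidden states.
4. **Information-gain fusion.** Each local dimension x_i and each
   context timestep t is scored by the information gain
   IG = H(feature) − H(feature | label) between its activation and the
   label; the IG values are normalized to fusion weights w_x (over local
   dimensions) and w_h (over timesteps). Both channels are linearly
   projected to a common width d_f; the weighted local vector is
   broadcast across timesteps and added to the weighted projected
   context rows, giving a fused sequence F of shape T × d_f.
5. **Attention pooling.** A learnable query q scores each fused row,
   score_t = qᵀ tanh(W F_t + b); a masked, max-stabilized softmax gives
   attention weights α_t, and the global vector is c = Σ_t α_t F_t.
6. **Output head.** The default head is linear → ReLU → linear →
   sigmoid on c. A `literal` head variant (sigmoid → ReLU → sigmoid on
   a single node) is selectable for ablations; note its first sigmoid
   maps into (0, 1), so its final probability is confined to
   [0.5, σ(1) ≈ 0.73] and it cannot assign the negative class under the
   strict 0.5 decision rule — which is why it is not the default.
   A probability strictly greater than 0.5 yields label 1.

The network and all gradients are implemented directly in NumPy
(analytic backpropagation, verified against central differences and
naive-loop oracles); there is no deep-learning-framework dependency.

## Information-gain estimation

Continuous activations are discretized per dimension by quantile
binning with B = 10 bins over a reference sample of the training split.
Features with at most B distinct values are binned by value instead:
quantile edges collapse on heavily tied data (e.g. 0/1 presence
features) and would otherwise merge distinct values into one bin. IG is
computed from the resulting contingency table with base-2 logarithms;
ε = 1e−12 guards the denominators inside the logarithm (an additive ε
would bias the IG of constant features away from exactly 0). By
symmetry of mutual information the estimate equals
H(label) − H(label | bin), so a perfectly label-aligned feature on
balanced classes scores 1 bit.

IG of a context *timestep* (a vector) is defined as the mean of the
per-dimension IG values at that timestep, computed over the samples for
which the timestep is real; this gives one scalar per timestep, matching
the normalization of w_h over t. If every IG is zero (e.g. untrained
features), the weights fall back to uniform.

Fusion weights are recomputed at the start of every epoch from the
first `ig_sample` (default 512) training documents, held constant for
that epoch's gradient steps (no gradient flows through the entropy
estimate), recomputed once more after the final epoch, and frozen for
inference — so inference is a deterministic function of the saved model.

## Training

Stratified 80/20 train/test split; vocabulary (top-N by frequency, ties
broken lexicographically, PAD/UNK reserved) built from the training
split only; mini-batch Adam (optionally with decoupled weight decay) on
binary cross-entropy. A single seed drives the split, parameter
initialization and shuffling, so identical configuration reproduces
identical weights, predictions, reports and manifests byte for byte.

Default hyperparameters follow the reference configuration: 100-d
embeddings, 3 × 128 convolution filters, 128 LSTM units per direction,
fused width 256, Adam at learning rate 1e-3, batch size 32, decision
threshold 0.5, truncation at 128 tokens (microblogs are short; the
synthetic corpora below never exceed ~101 tokens, and truncating below
a corpus's length range clips planted signal out of long documents).

## Evaluation

Accuracy, precision, recall and F1 come from the confusion matrix with
the zero-denominator convention "metric = 0 plus a warning". Two AUC
variants are reported side by side: the standard trapezoidal ROC
integral (ties averaged) and the single-operating-point summary
(1 + TPR − FPR)/2 at the 0.5 threshold. The confidence score is
1 − (1/N) Σ H₂(p_i) with H₂ the base-2 Bernoulli entropy, which is
already bounded in [0, 1]: 0 means every prediction sits at p = 0.5,
1 means every prediction is fully confident. Reports also carry ×100
"percent" renderings of all rates.

## Lexical analytics

Per-word information gain uses document-level presence/absence against
the label — the same IG statistic as the fusion layer, applied to the
lexicon — and ranks words descending (lexicographic tie-break). The
log-likelihood-ratio ranking is Dunning's G² on the 2 × 2 token-count
table (word vs. rest, class vs. class), signed by which class over-uses
the word; it is cross-checked in the tests against an independent
likelihood-ratio computation. POS tagging is out of scope: the report
consumes pre-tagged token/tag pairs from any external tagger and
computes per-class tag proportions and pronoun-person proportions
(first singular / first plural / second / third) from a user-editable
pronoun lexicon with built-in Chinese and English defaults.

## Synthetic corpora

The generator emulates the structure of a labeled microblog corpus
without shipping any real suicide-related lexicon: balanced classes of
5–100-token documents over an alphabetic pseudo-word noise vocabulary
(500 words by default), one or more planted signal words with
class-conditional document probabilities (p_pos ≥ p_neg), verbatim
platform artifacts (topic hashtags, @mentions, URLs, repost markers) at
a 10% document rate so the cleaning rules are observable, and 2% junk
records under the five-character keep threshold. Noise words are purely
alphabetic so the cleaning stage's digit normalization leaves them
intact. For a single signal word the generative model admits a
closed-form Bayes-optimal accuracy, which the training benchmarks use
as a yardstick.

What the generator does *not* emulate — and what passing benchmarks
therefore do not demonstrate — includes real Chinese morphology and
segmentation ambiguity, Zipfian vocabulary distributions, emoji
semantics, topic drift, label noise, and the subtle/figurative language
that makes real suicidal-ideation detection hard. The benchmarks
validate the machinery (optimization, fusion, metrics, determinism),
not clinical performance.

## Benchmark problem sizes

The synthetic benchmarks and the acceptance script run the full
topology at reduced widths — 32-d embeddings, 3 × 16 filters, 32 LSTM
units, fused width 64 — with Adam at learning rate 1e-2 and decoupled
weight decay 1e-3, chosen so a 500-document run trains in well under a
minute on one CPU while remaining over-parameterized for the planted-
signal tasks. The weight decay matters at this scale: with 500 distinct
noise words and only 400 training documents, an unregularized run
memorizes chance noise-word/label correlations and leaves a few
held-out errors even on a perfectly separable corpus.

Two standard benchmark corpora are used: n = 500 with p_pos = 1.0 /
p_neg = 0.0 (Bayes accuracy 1.0; the trained model reaches held-out
accuracy 1.0 within 10 epochs) and n = 2000 with p_pos = 0.9 /
p_neg = 0.1 (Bayes accuracy 0.9; held-out accuracy lands within 5
points of it in 10 epochs).

## Numerical and degenerate-input choices

- Short sequences are right-padded with masked zero rows to the largest
  kernel size; a convolution window is pooled only if it lies fully
  inside the real sequence (sequences shorter than the kernel keep
  their single leading zero-padded window), making pooled features
  independent of batch padding width — batched and one-by-one inference
  agree to machine precision.
- Masked timesteps contribute zero rows in both channels and are
  excluded from the attention softmax (max-subtraction stabilized).
- Probability exactly 0.5 maps to the negative class (strict
  "exceeding").
- Empty batches, fully masked sequences, single-class corpora, unknown
  registry names and out-of-range indices raise typed errors
  (`DegenerateInputError`, `TrainingError`, `ConfigError`, `DataError`)
  rather than producing NaNs.
- Model weights are serialized with fixed zip metadata so identical
  runs produce byte-identical model directories; manifests store paths
  relative to the manifest file and record SHA-256 digests, never
  wall-clock timings (timings go to the stderr log).

## Known limitations

- The composite embedding is not a contextual language model; on real
  Chinese microblogs the intended configuration plugs a pretrained
  encoder into the adapter seam, and results on synthetic corpora say
  nothing about that configuration's quality.
- The IG estimator treats feature dimensions independently; redundant
  correlated dimensions share weight rather than being de-duplicated.
- Exact-tie attention scores and exactly-equal pooled activations
  resolve by argmax order (first occurrence), a measure-zero event for
  continuous weights.
- Training is single-threaded NumPy; the default full-width
  configuration is CPU-practical only for corpora in the tens of
  thousands of documents.
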