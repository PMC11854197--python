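# igfuse

Dual-channel short-text classification with information-gain-weighted
attention fusion, built for detecting suicidal ideation in microblog
posts (Weibo-style short texts).

## The problem

Suicidal ideation often surfaces first in short social-media posts —
noisy, informal text full of platform artifacts (topic hashtags,
`@user` mentions, URLs, `[reposts]` markers). Detecting it is a binary
classification problem, P(y = 1 | text), where the decisive evidence
can be either *local* (specific words and phrases: "cut wrists",
"despair") or *contextual* (how the sentence unfolds). `igfuse` is for
researchers in clinical NLP and computational mental health who want a
transparent, dependency-light, fully reproducible implementation of a
dual-channel architecture for this task, with the surrounding pipeline
(cleaning, synthetic benchmarking, evaluation, lexical analytics)
included.

## The model

Two encoders read the same embedded token sequence
H = [h₁, …, h_T] (token + segment + position embeddings, hᵢ ∈ ℝᵈ):

* **Local channel** — parallel valid convolutions with kernel sizes
  (5, 7, 3), 128 filters each, ReLU, max-pooling over time,
  concatenated into x (TextCNN-style n-gram features);
* **Context channel** — a BiLSTM (128 units per direction) producing
  per-timestep bidirectional states H_t = [h_t→ ; h_t←].

The channels are fused by **information-gain weighting**: each local
dimension xᵢ and each context timestep t is scored by
IG = H(feature) − H(feature | y), estimated by quantile binning, and
the normalized weights

  w_{xᵢ} = IG(xᵢ) / Σᵢ IG(xᵢ),  w_{h_t} = IG(h_t) / Σₜ IG(h_t)

rescale the two feature sets before both are projected to a common
width and combined into a fused sequence F. A learnable-query
attention, score_t = qᵀ tanh(W F_t + b) with a masked softmax, pools F
into the global vector c, and a small fully connected head maps c to
P(y = 1 | c); probability > 0.5 yields the positive label.

Evaluation reports accuracy, precision, recall, F1, two AUC variants
(trapezoidal ROC integral and the single-point (1 + TPR − FPR)/2), and
a prediction-entropy confidence score, 1 − (1/N) Σ H₂(pᵢ) ∈ [0, 1],
where H₂ is the base-2 Bernoulli entropy — higher means a more
confident model. Corpus-level analytics rank words by information gain
and by signed Dunning G² (log-likelihood ratio), and report POS/pronoun
distributions over externally tagged input.

The network and all gradients are pure NumPy (analytic
backpropagation); a pretrained contextual encoder can be plugged in
behind the `"bert-adapter"` seam but is not required or shipped. See
`docs/methods.md` for the full model account.

## Worked example

Since no real corpus ships with the package, the synthetic generator
plants a signal word ("despair") in every positive document and in no
negative one (so the Bayes-optimal accuracy is 1.0), and the full
pipeline trains on it:

```python
import numpy as np
from igfuse import (GeneratorSpec, SignalWord, generate_corpus, preprocess,
                    TrainConfig, ModelConfig, train, evaluate, word_ig)

spec = GeneratorSpec(n_docs=500,
                     signal_words=(SignalWord("despair", 1.0, 0.0),),
                     seed=42)
docs = preprocess(generate_corpus(spec))

model_cfg = ModelConfig(embedding_dim=32, filters_per_size=16, lstm_hidden=32,
                        fused_dim=64, attn_dim=32, head_hidden=32)
trained = train(docs,
                TrainConfig(seed=7, epochs=10, learning_rate=1e-2,
                            weight_decay=1e-3),
                model_cfg)

test_ids = set(trained.test_doc_ids)
test_docs = [d for d in docs if d.doc_id in test_ids]
preds, _ = trained.predict_docs(test_docs)
labels = np.array([d.label for d in test_docs if d.kept])
probs = np.array([p.probability for p in preds])
report = evaluate(labels, probs)
print(f"held-out accuracy   {report.accuracy:.3f}")
print(f"AUC (trapezoid)     {report.auc_trapezoid:.3f}")
print(f"confidence score    {report.entropy_score:.3f}")
for s in word_ig(docs, top=3):
    print(f"  {s.rank}. {s.word:8s} IG={s.ig_bits:.3f} bits  G2={s.llr:+.1f}")
```

prints

```
held-out accuracy   0.980
AUC (trapezoid)     1.000
confidence score    0.990
  1. despair  IG=1.000 bits  G2=+354.5
  2. wagk     IG=0.026 bits  G2=-15.8
  3. wacy     IG=0.023 bits  G2=-11.3
```

The planted word carries exactly 1 bit of information gain (it
determines the balanced label perfectly) and dominates every noise
word; the trained model separates the held-out classes almost
perfectly, and the confidence score near 1 says its probabilities sit
close to 0 and 1. The same stages are available from the shell:

```bash
igfuse generate --spec spec.yaml --out corpus.jsonl
igfuse prep     --input corpus.jsonl --output clean.jsonl
igfuse train    --corpus clean.jsonl --config config.yaml --out model/
igfuse evaluate --model model/ --corpus clean.jsonl --report report.json
igfuse predict  --model model/ --input new.jsonl --output preds.jsonl
igfuse analyze  --corpus clean.jsonl --top 20 --out words.csv
```

Every run writes a manifest with the config snapshot, seed and SHA-256
digests of its inputs and outputs; identical config + seed reproduces
every artifact byte for byte.

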