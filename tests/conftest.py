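"""Shared fixtures: model configurations sized for fast CPU runs and
session-scoped synthetic corpora / trained models reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from igfuse import (
    GeneratorSpec,
    ModelConfig,
    SignalWord,
    TrainConfig,
    generate_corpus,
    preprocess,
    train,
)

# Benchmark-scale architecture for training tests: same topology as the
# full model, reduced widths so a training run takes seconds on one CPU.
SMALL_MODEL = ModelConfig(
    embedding_dim=32,
    max_len=128,
    kernel_sizes=(5, 7, 3),
    filters_per_size=16,
    lstm_hidden=32,
    fused_dim=64,
    attn_dim=32,
    head_hidden=32,
)

# Minimal architecture for mechanics tests (determinism, persistence).
TINY_MODEL = ModelConfig(
    embedding_dim=8,
    max_len=40,
    kernel_sizes=(3, 2),
    filters_per_size=4,
    lstm_hidden=6,
    fused_dim=12,
    attn_dim=8,
    head_hidden=8,
)

# Optimization settings for the synthetic benchmarks.
BENCH_LR = 1e-2
BENCH_WD = 1e-3


def tiny_corpus(n_docs: int = 120, seed: int = 21, p_pos: float = 1.0,
                p_neg: float = 0.0):
    spec = GeneratorSpec(
        n_docs=n_docs,
        doc_length=(5, 20),
        signal_words=(SignalWord("despair", p_pos, p_neg),),
        noise_vocab_size=50,
        artifact_rate=0.05,
        junk_rate=0.0,
        seed=seed,
    )
    return preprocess(generate_corpus(spec))


@pytest.fixture(scope="session")
def perfect_corpus():
    """n=500 corpus whose signal word appears in every positive and no
    negative document (Bayes accuracy 1)."""
    spec = GeneratorSpec(
        n_docs=500,
        signal_words=(SignalWord("despair", 1.0, 0.0),),
        seed=11,
    )
    return preprocess(generate_corpus(spec))


@pytest.fixture(scope="session")
def noisy_spec():
    return GeneratorSpec(
        n_docs=2000,
        signal_words=(SignalWord("despair", 0.9, 0.1),),
        seed=13,
    )


@pytest.fixture(scope="session")
def noisy_corpus(noisy_spec):
    return preprocess(generate_corpus(noisy_spec))


@pytest.fixture(scope="session")
def trained_noisy(noisy_corpus):
    """Model trained on the 0.9/0.1 planted-signal corpus."""
    return train(
        noisy_corpus,
        TrainConfig(seed=5, epochs=10, learning_rate=BENCH_LR,
                    weight_decay=BENCH_WD),
        SMALL_MODEL,
    )


def held_out_accuracy(trained, docs):
    """Accuracy of a trained model on its held-out split."""
    test_ids = set(trained.test_doc_ids)
    test_docs = [d for d in docs if d.doc_id in test_ids]
    preds, _ = trained.predict_docs(test_docs)
    labels = np.array([d.label for d in test_docs if d.kept])
    hard = np.array([p.label for p in preds])
    return float((labels == hard).mean())
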