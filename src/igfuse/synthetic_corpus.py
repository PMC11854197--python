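"""Synthetic labeled microblog corpora with planted lexical signal.

The generator emulates the structure of a crawled short-text corpus:
two classes of short documents built from a shared noise vocabulary,
with a small set of "signal" words that occur with elevated probability
in the positive (suicidal-ideation) class, plus platform artifacts
(topic hashtags, @mentions, URLs, repost markers) and occasional junk
records shorter than the five-character keep threshold.

Because the signal words have a known occurrence model, downstream
stages can be validated against closed-form yardsticks such as
:func:`bayes_optimal_accuracy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, IgfuseError
from .textprep import RawDocument

_ARTIFACT_TEMPLATES = (
    "#SuperTopic{i}#",
    "@user{i}",
    "http://t.cn/x{i}",
    "[reposts]",
)

_JUNK_TEXTS = ("ok", "hm!!", "...", "a b", ":-)")


@dataclass(frozen=True)
class SignalWord:
    """A planted word with per-class document occurrence probabilities."""

    word: str
    p_pos: float
    p_neg: float

    def __post_init__(self) -> None:
        for name, p in (("p_pos", self.p_pos), ("p_neg", self.p_neg)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        if self.p_pos < self.p_neg:
            raise ConfigError(
                f"signal word {self.word!r}: p_pos ({self.p_pos}) must be "
                f">= p_neg ({self.p_neg})"
            )


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for a synthetic corpus.

    Defaults mirror a balanced short-text corpus: documents of 5-100
    tokens, a shared noise vocabulary, a 10% chance of a platform
    artifact per document and a 2% rate of sub-threshold junk records.
    """

    n_docs: int = 2000
    class_balance: float = 0.5
    doc_length: tuple[int, int] = (5, 100)
    signal_words: tuple[SignalWord, ...] = (
        SignalWord("despair", 0.9, 0.1),
    )
    noise_vocab_size: int = 500
    artifact_rate: float = 0.1
    junk_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ConfigError("n_docs must be >= 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigError("class_balance must be in (0,1)")
        lo, hi = self.doc_length
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid doc_length range {self.doc_length}")
        for name, p in (
            ("artifact_rate", self.artifact_rate),
            ("junk_rate", self.junk_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        if self.noise_vocab_size < 1:
            raise ConfigError("noise_vocab_size must be >= 1")


def noise_vocabulary(size: int) -> list[str]:
    """Deterministic ASCII pseudo-word inventory (disjoint from signal).

    Words are purely alphabetic (base-26 suffixes) so that the cleaning
    stage's digit normalization leaves them untouched.
    """
    if size > 26**3:
        raise ConfigError(f"noise vocabulary capped at {26**3} words")
    words = []
    for i in range(size):
        suffix, j = "", i
        for _ in range(3):
            suffix = chr(ord("a") + j % 26) + suffix
            j //= 26
        words.append("w" + suffix)
    return words


def generate_corpus(spec: GeneratorSpec) -> list[RawDocument]:
    """Draw a labeled corpus from the generative model.

    Per document: label ~ Bernoulli(class_balance); length uniform in
    ``doc_length``; tokens drawn uniformly from the noise vocabulary;
    each signal word independently inserted at a random position with
    its class-conditional probability.  With probability
    ``artifact_rate`` one platform artifact is injected verbatim, and
    with probability ``junk_rate`` the document body is replaced by a
    junk record shorter than five characters.  The same spec (including
    seed) reproduces the corpus byte for byte.
    """
    rng = np.random.default_rng(spec.seed)
    noise = noise_vocabulary(spec.noise_vocab_size)
    signal_set = {sw.word for sw in spec.signal_words}
    if signal_set & set(noise):
        raise ConfigError("signal words must be disjoint from noise vocabulary")

    docs: list[RawDocument] = []
    lo, hi = spec.doc_length
    for i in range(spec.n_docs):
        label = int(rng.random() < spec.class_balance)
        if rng.random() < spec.junk_rate:
            text = _JUNK_TEXTS[int(rng.integers(len(_JUNK_TEXTS)))]
            docs.append(RawDocument(f"doc{i:06d}", text, label))
            continue
        length = int(rng.integers(lo, hi + 1))
        tokens = [noise[j] for j in rng.integers(0, len(noise), size=length)]
        for sw in spec.signal_words:
            p = sw.p_pos if label == 1 else sw.p_neg
            if rng.random() < p:
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, sw.word)
        if rng.random() < spec.artifact_rate:
            template = _ARTIFACT_TEMPLATES[
                int(rng.integers(len(_ARTIFACT_TEMPLATES)))
            ]
            artifact = template.format(i=int(rng.integers(100)))
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens.insert(pos, artifact)
        docs.append(RawDocument(f"doc{i:06d}", " ".join(tokens), label))
    return docs


def bayes_optimal_accuracy(spec: GeneratorSpec) -> float:
    """Closed-form accuracy of the optimal classifier for one signal word.

    The optimal rule observes presence/absence of the single signal word
    and picks the maximum-posterior class; the accuracy enumerates the
    2x2 outcome table of (presence, label).
    """
    if len(spec.signal_words) != 1:
        raise IgfuseError(
            "bayes_optimal_accuracy supports exactly one signal word"
        )
    sw = spec.signal_words[0]
    b = spec.class_balance
    # Joint probabilities over (word present?, label).
    acc = 0.0
    for present in (True, False):
        p1 = (sw.p_pos if present else 1 - sw.p_pos) * b
        p0 = (sw.p_neg if present else 1 - sw.p_neg) * (1 - b)
        acc += max(p1, p0)
    return acc
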