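"""Corpus-level lexical analytics: per-word IG, log-likelihood ratio,
and part-of-speech / pronoun distribution reports.

``word_ig`` ranks vocabulary items by the information gain between
document-level presence/absence of the word and the binary class
label — the same statistic the fusion layer uses for features, applied
to the lexicon.  ``word_llr`` ranks words by Dunning's log-likelihood
ratio G² computed from the 2x2 token-count table (word vs. rest of
vocabulary, class 1 vs. class 0), signed so that positive values mark
words over-used by the positive class.

POS tagging itself is out of scope: ``pos_report`` consumes pre-tagged
input (parallel token/tag lists) from any external tagger and reports
per-class tag proportions plus pronoun-person proportions driven by a
configurable pronoun lexicon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import CapabilityError, DataError
from .ig_fusion import _mutual_information_bits
from .textprep import CleanDocument

import numpy as np


@dataclass(frozen=True)
class WordStats:
    word: str
    df_pos: int
    df_neg: int
    ig_bits: float
    llr: float
    rank: int


# Minimal built-in pronoun lexicon (Chinese + English); user-extensible.
DEFAULT_PRONOUN_LEXICON: dict[str, str] = {
    "我": "first_singular", "I": "first_singular", "i": "first_singular",
    "me": "first_singular", "my": "first_singular", "mine": "first_singular",
    "我们": "first_plural", "咱们": "first_plural", "we": "first_plural",
    "us": "first_plural", "our": "first_plural", "ours": "first_plural",
    "你": "second", "您": "second", "你们": "second", "you": "second",
    "your": "second", "yours": "second",
    "他": "third", "她": "third", "它": "third", "他们": "third",
    "她们": "third", "它们": "third", "he": "third", "she": "third",
    "him": "third", "her": "third", "it": "third", "they": "third",
    "them": "third", "their": "third",
}

PRONOUN_CATEGORIES = ("first_singular", "first_plural", "second", "third")


@dataclass
class PosReport:
    """Per-class tag and pronoun-person proportions (each sums to 1)."""

    tag_proportions: dict[str, float] = field(default_factory=dict)
    pronoun_proportions: dict[str, float] = field(default_factory=dict)


def _split_classes(
    docs: list[CleanDocument],
) -> tuple[list[CleanDocument], list[CleanDocument]]:
    kept = [d for d in docs if d.kept]
    pos = [d for d in kept if d.label == 1]
    neg = [d for d in kept if d.label == 0]
    if not pos or not neg:
        raise DataError("both classes must be present")
    return pos, neg


def presence_ig(
    df_pos: int, n_pos: int, df_neg: int, n_neg: int, eps: float = 1e-12
) -> float:
    """IG in bits from a presence/absence vs. label contingency table."""
    joint = np.array(
        [
            [float(df_neg), float(df_pos)],          # word present
            [float(n_neg - df_neg), float(n_pos - df_pos)],  # absent
        ]
    )
    return _mutual_information_bits(joint, eps)


def word_llr_from_counts(
    k1: int, n1: int, k2: int, n2: int, eps: float = 1e-12
) -> float:
    """Signed Dunning G² for one word from token counts.

    ``k1``/``n1`` are the word count and total token count in class 1,
    ``k2``/``n2`` likewise for class 2.  G² = 2 * sum O ln(O/E) over
    the 2x2 table; the sign is positive when the word's relative
    frequency is higher in class 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise DataError("class token totals must be positive")
    table = np.array(
        [[k1, n1 - k1], [k2, n2 - k2]], dtype=float
    )
    total = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    mask = table > 0
    g2 = 2.0 * float(
        (table[mask] * np.log(table[mask] / (expected[mask] + eps))).sum()
    )
    sign = 1.0 if (k1 / n1) >= (k2 / n2) else -1.0
    return sign * g2


def word_ig(docs: list[CleanDocument], top: int | None = None) -> list[WordStats]:
    """Per-word IG and LLR over a labeled corpus, sorted by IG descending.

    IG uses document presence/absence; LLR uses token counts.  Ties are
    broken lexicographically so the ranking is deterministic.
    """
    pos, neg = _split_classes(docs)
    df_pos: Counter[str] = Counter()
    df_neg: Counter[str] = Counter()
    tf_pos: Counter[str] = Counter()
    tf_neg: Counter[str] = Counter()
    for d in pos:
        df_pos.update(set(d.tokens))
        tf_pos.update(d.tokens)
    for d in neg:
        df_neg.update(set(d.tokens))
        tf_neg.update(d.tokens)
    vocab = sorted(set(df_pos) | set(df_neg))
    if not vocab:
        raise DataError("empty vocabulary")
    n_pos, n_neg = len(pos), len(neg)
    t_pos, t_neg = sum(tf_pos.values()), sum(tf_neg.values())
    scored = []
    for w in vocab:
        ig = presence_ig(df_pos[w], n_pos, df_neg[w], n_neg)
        llr = word_llr_from_counts(tf_pos[w], t_pos, tf_neg[w], t_neg)
        scored.append((w, df_pos[w], df_neg[w], ig, llr))
    scored.sort(key=lambda rec: (-rec[3], rec[0]))
    if top is not None:
        scored = scored[:top]
    return [
        WordStats(word=w, df_pos=dp, df_neg=dn, ig_bits=ig, llr=llr, rank=i + 1)
        for i, (w, dp, dn, ig, llr) in enumerate(scored)
    ]


def word_llr(
    counts_class1: dict[str, int], counts_class2: dict[str, int]
) -> dict[str, float]:
    """Signed G² per word from two class token-count dictionaries.

    Words absent from both classes are skipped.
    """
    n1 = sum(counts_class1.values())
    n2 = sum(counts_class2.values())
    out: dict[str, float] = {}
    for w in sorted(set(counts_class1) | set(counts_class2)):
        k1 = counts_class1.get(w, 0)
        k2 = counts_class2.get(w, 0)
        if k1 == 0 and k2 == 0:
            continue
        out[w] = word_llr_from_counts(k1, n1, k2, n2)
    return out


def pos_report(
    tagged_docs: list[dict],
    pronoun_lexicon: dict[str, str] | None = None,
) -> dict[int, PosReport]:
    """Tag and pronoun-person proportions per class.

    ``tagged_docs`` records need parallel ``tokens`` and ``tags`` lists
    plus a binary ``label``; tags come from any external tagger.
    Returns ``{0: PosReport, 1: PosReport}``.
    """
    lexicon = pronoun_lexicon or DEFAULT_PRONOUN_LEXICON
    by_class: dict[int, tuple[Counter, Counter]] = {
        0: (Counter(), Counter()),
        1: (Counter(), Counter()),
    }
    for rec in tagged_docs:
        if "tags" not in rec or rec.get("tags") is None:
            raise CapabilityError(
                "untagged corpus: run an external POS tagger and supply "
                "parallel 'tokens' and 'tags' lists"
            )
        tokens, tags = rec["tokens"], rec["tags"]
        if len(tokens) != len(tags):
            raise DataError(
                f"record {rec.get('id')!r}: tokens and tags differ in length"
            )
        label = int(rec["label"])
        tag_counts, pron_counts = by_class[label]
        tag_counts.update(tags)
        for tok in tokens:
            cat = lexicon.get(tok)
            if cat is not None:
                pron_counts[cat] += 1
    reports: dict[int, PosReport] = {}
    for label, (tag_counts, pron_counts) in by_class.items():
        tag_total = sum(tag_counts.values())
        pron_total = sum(pron_counts.values())
        reports[label] = PosReport(
            tag_proportions={
                t: c / tag_total for t, c in sorted(tag_counts.items())
            }
            if tag_total
            else {},
            pronoun_proportions={
                cat: (pron_counts[cat] / pron_total if pron_total else 0.0)
                for cat in PRONOUN_CATEGORIES
            }
            if pron_total
            else {},
        )
    return reports


def stats_to_csv(stats: list[WordStats]) -> str:
    lines = ["word,freq_pos,freq_neg,ig_bits,llr,rank"]
    for s in stats:
        lines.append(
            f"{s.word},{s.df_pos},{s.df_neg},{s.ig_bits:.6g},{s.llr:.6g},{s.rank}"
        )
    return "\n".join(lines) + "\n"
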