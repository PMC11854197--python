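"""Word-level IG ranking, log-likelihood ratio and POS reports."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from igfuse import pos_report, word_ig, word_llr
from igfuse.errors import CapabilityError, DataError
from igfuse.ig_fusion import information_gain
from igfuse.lexstats import presence_ig, word_llr_from_counts
from igfuse.textprep import CleanDocument


def _doc(i, tokens, label):
    return CleanDocument(
        doc_id=f"d{i}", cleaned_text=" ".join(tokens),
        tokens=tuple(tokens), kept=True, label=label,
    )


def _corpus(pos_docs, neg_docs):
    docs = [_doc(i, t, 1) for i, t in enumerate(pos_docs)]
    docs += [_doc(100 + i, t, 0) for i, t in enumerate(neg_docs)]
    return docs


def test_perfectly_separating_word_ranks_first_with_one_bit():
    docs = _corpus(
        [["die", "a"], ["die", "b"], ["die", "c"], ["die", "a"]],
        [["a", "b"], ["b", "c"], ["c", "a"], ["a", "c"]],
    )
    stats = word_ig(docs)
    assert stats[0].word == "die"
    assert stats[0].rank == 1
    assert stats[0].ig_bits == pytest.approx(1.0)


def test_word_in_every_document_has_zero_ig():
    docs = _corpus([["x", "a"], ["x", "b"]], [["x", "c"], ["x", "d"]])
    by_word = {s.word: s for s in word_ig(docs)}
    assert by_word["x"].ig_bits == pytest.approx(0.0)


def test_planted_word_outranks_all_noise_words(noisy_corpus):
    """On a 2000-document corpus with one word planted at 0.9/0.1, that
    word attains rank 1, confirmed by a brute-force contingency oracle."""
    stats = word_ig(noisy_corpus)
    assert stats[0].word == "despair"
    # brute-force oracle for the same quantity
    kept = [d for d in noisy_corpus if d.kept]
    n_pos = sum(d.label for d in kept)
    n_neg = len(kept) - n_pos
    df_pos = sum(1 for d in kept if d.label == 1 and "despair" in d.tokens)
    df_neg = sum(1 for d in kept if d.label == 0 and "despair" in d.tokens)
    joint = np.array(
        [[df_neg, df_pos], [n_neg - df_neg, n_pos - df_pos]], float
    )
    n = joint.sum()
    pr = joint.sum(axis=1) / n
    pc = joint.sum(axis=0) / n
    oracle = sum(
        joint[i, j] / n * np.log2(joint[i, j] / n / (pr[i] * pc[j]))
        for i in range(2) for j in range(2) if joint[i, j] > 0
    )
    assert stats[0].ig_bits == pytest.approx(float(oracle), abs=1e-9)


def test_ig_invariant_to_document_order_and_duplication(noisy_corpus):
    sub = noisy_corpus[:300]
    base = word_ig(sub)
    reordered = word_ig(sub[::-1])
    doubled = word_ig(sub + sub)
    for a, b, c in zip(base, reordered, doubled):
        assert a.word == b.word == c.word
        assert a.ig_bits == pytest.approx(b.ig_bits)
        assert a.ig_bits == pytest.approx(c.ig_bits)


def test_presence_ig_consistent_with_binned_estimator():
    """Document presence/absence IG equals the generic estimator applied
    to the 0/1 presence feature with 2 bins."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        n_pos, n_neg = int(rng.integers(2, 30)), int(rng.integers(2, 30))
        df_pos = int(rng.integers(0, n_pos + 1))
        df_neg = int(rng.integers(0, n_neg + 1))
        presence = np.array(
            [1.0] * df_pos + [0.0] * (n_pos - df_pos)
            + [1.0] * df_neg + [0.0] * (n_neg - df_neg)
        )
        labels = np.array([1] * n_pos + [0] * n_neg)
        direct = presence_ig(df_pos, n_pos, df_neg, n_neg)
        binned = information_gain(presence, labels, bins=2)
        assert direct == pytest.approx(binned, abs=1e-9)


def test_llr_zero_for_proportional_rows():
    assert word_llr_from_counts(5, 100, 10, 200) == pytest.approx(0.0, abs=1e-9)


def test_llr_sign_indicates_overusing_class():
    assert word_llr_from_counts(10, 100, 0, 100) > 0
    counts = word_llr({"w": 0, "v": 10}, {"w": 10, "v": 10})
    assert counts["w"] < 0


def test_llr_matches_scipy_log_likelihood_oracle():
    """Signed G2 magnitude equals scipy's log-likelihood-ratio statistic
    on the 2x2 table (k1=10, n1=100, k2=1, n2=100)."""
    k1, n1, k2, n2 = 10, 100, 1, 100
    g2, _, _, _ = chi2_contingency(
        [[k1, n1 - k1], [k2, n2 - k2]],
        correction=False,
        lambda_="log-likelihood",
    )
    ours = word_llr_from_counts(k1, n1, k2, n2)
    assert ours == pytest.approx(float(g2), rel=1e-9)
    assert ours > 0


def test_word_absent_from_both_classes_skipped():
    out = word_llr({"a": 3, "b": 0}, {"a": 1, "b": 0})
    assert "b" not in out and "a" in out


def test_word_ig_requires_both_classes():
    docs = [_doc(0, ["a"], 1), _doc(1, ["b"], 1)]
    with pytest.raises(DataError):
        word_ig(docs)


# -- POS / pronoun reports -------------------------------------------


def test_single_tag_document_gives_full_proportion():
    tagged = [{"id": "1", "tokens": ["run", "jump"], "tags": ["v", "v"],
               "label": 1}]
    reports = pos_report(tagged)
    assert reports[1].tag_proportions == {"v": 1.0}


def test_equal_tag_groups_split_evenly():
    tagged = [{"id": "1", "tokens": ["run", "dog"], "tags": ["v", "n"],
               "label": 0}]
    assert pos_report(tagged)[0].tag_proportions == {"n": 0.5, "v": 0.5}


def test_verb_share_on_synthetic_tagged_fixture():
    """A fixture with 3477 verb tags out of 10000 reproduces the 0.3477
    verb proportion exactly."""
    n_verbs, n_total = 3477, 10000
    tags = ["v"] * n_verbs + ["n"] * (n_total - n_verbs)
    tagged = [{"id": "1", "tokens": ["tok"] * n_total, "tags": tags,
               "label": 1}]
    reports = pos_report(tagged)
    assert reports[1].tag_proportions["v"] == pytest.approx(0.3477, abs=1e-9)
    assert sum(reports[1].tag_proportions.values()) == pytest.approx(1.0)


def test_pronoun_person_proportions():
    tagged = [{
        "id": "1",
        "tokens": ["我", "我", "我们", "you", "dog"],
        "tags": ["r", "r", "r", "r", "n"],
        "label": 1,
    }]
    pron = pos_report(tagged)[1].pronoun_proportions
    assert pron["first_singular"] == pytest.approx(0.5)
    assert pron["first_plural"] == pytest.approx(0.25)
    assert pron["second"] == pytest.approx(0.25)
    assert pron["third"] == 0.0
    assert sum(pron.values()) == pytest.approx(1.0)


def test_untagged_corpus_raises_capability_error():
    with pytest.raises(CapabilityError):
        pos_report([{"id": "1", "tokens": ["a"], "label": 0}])


def test_mismatched_tokens_and_tags_rejected():
    with pytest.raises(DataError):
        pos_report([{"id": "1", "tokens": ["a", "b"], "tags": ["n"],
                     "label": 0}])
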