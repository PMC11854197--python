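"""Information-gain estimation, fusion weights, fusion and attention."""

import itertools
import math
import types
import warnings

import numpy as np
import pytest

from igfuse import (
    AttentionPooling,
    FusionLayer,
    FusionWeights,
    attend,
    compute_fusion_weights,
    fuse,
    information_gain,
)
from igfuse.errors import DataError, DegenerateInputError, EstimationError
from igfuse.ig_fusion import _normalize_ig, masked_softmax


def exhaustive_ig(table):
    """Discrete-entropy oracle: IG = H(bin) - H(bin|label) from counts.

    ``table[b][y]`` is the count of samples in bin b with label y.
    Computed with plain log2 sums, independent of the estimator code.
    """
    table = np.asarray(table, float)
    n = table.sum()
    h = lambda probs: -sum(p * math.log2(p) for p in probs if p > 0)
    H_bin = h(table.sum(axis=1) / n)
    H_cond = 0.0
    for y in (0, 1):
        col = table[:, y]
        ny = col.sum()
        if ny > 0:
            H_cond += (ny / n) * h(col / ny)
    return H_bin - H_cond


def _table_to_samples(table):
    values, labels = [], []
    for b, row in enumerate(table):
        for y, count in enumerate(row):
            values += [float(b)] * count
            labels += [y] * count
    return np.array(values), np.array(labels)


def test_feature_equal_to_label_gives_one_bit():
    labels = np.array([0, 1] * 8)
    assert information_gain(labels.astype(float), labels) == pytest.approx(1.0)


def test_constant_feature_gives_zero():
    labels = np.array([0, 1] * 8)
    assert information_gain(np.ones(16), labels) == pytest.approx(0.0)


def test_two_bin_example_value():
    """Bins A:(3 pos, 1 neg) and B:(1 pos, 3 neg) give IG
    = H(0.5) - 0.5 H(0.75) - 0.5 H(0.25) ~ 0.1887 bits."""
    values, labels = _table_to_samples([[1, 3], [3, 1]])
    assert information_gain(values, labels) == pytest.approx(0.18872, abs=1e-4)


def test_ig_matches_exhaustive_oracle_on_all_small_tables():
    """Estimator equals the discrete-entropy oracle on every 2-bin x
    2-label contingency table with cell counts <= 6."""
    checked = 0
    for a, b, c, d in itertools.product(range(7), repeat=4):
        table = [[a, b], [c, d]]
        values, labels = _table_to_samples(table)
        if values.size < 2:
            continue
        if len(np.unique(labels)) < 2:
            continue
        got = information_gain(values, labels)
        assert got == pytest.approx(exhaustive_ig(table), abs=1e-9)
        checked += 1
    assert checked > 1000


def test_constant_labels_warn_and_return_zero():
    with pytest.warns(UserWarning):
        out = information_gain(np.array([0.0, 1.0, 2.0]), np.array([1, 1, 1]))
    assert out == 0.0


def test_ig_needs_two_samples():
    with pytest.raises(EstimationError):
        information_gain(np.array([1.0]), np.array([1]))


def test_ig_is_nonnegative_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(2, 40))
        values = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            continue
        assert information_gain(values, labels) >= 0.0


# -- fusion weights ---------------------------------------------------


def test_normalized_ig_shares():
    assert np.allclose(
        _normalize_ig(np.array([0.2, 0.1, 0.1])), [0.5, 0.25, 0.25]
    )


def test_equal_ig_gives_uniform_weights():
    labels = np.tile([0, 1], 40)
    x = np.column_stack([labels, labels, labels]).astype(float)
    Hc = np.repeat(labels.astype(float), 2).reshape(80, 1, 2)
    w = compute_fusion_weights(x, Hc, labels, min_samples=64)
    assert np.allclose(w.w_x, 1 / 3)
    assert np.allclose(w.w_x.sum(), 1.0) and np.allclose(w.w_h.sum(), 1.0)


def test_single_informative_dimension_takes_all_weight():
    labels = np.tile([0, 1], 40)
    rng_const = np.ones(80)
    x = np.column_stack([labels.astype(float), rng_const, rng_const])
    Hc = labels.astype(float).reshape(80, 1, 1)
    w = compute_fusion_weights(x, Hc, labels, min_samples=64)
    assert np.allclose(w.w_x, [1.0, 0.0, 0.0])


def test_all_zero_ig_falls_back_to_uniform():
    labels = np.tile([0, 1], 40)
    x = np.ones((80, 4))
    Hc = np.ones((80, 2, 3))
    w = compute_fusion_weights(x, Hc, labels, min_samples=64)
    assert np.allclose(w.w_x, 0.25)
    assert np.allclose(w.w_h, 0.5)


def test_min_samples_enforced():
    labels = np.array([0, 1] * 4)
    with pytest.raises(EstimationError):
        compute_fusion_weights(
            np.ones((8, 2)), np.ones((8, 1, 2)), labels, min_samples=64
        )


def test_fusion_weights_validate():
    with pytest.raises(DataError):
        FusionWeights(w_x=np.array([0.5, 0.6]), w_h=np.array([1.0]))
    with pytest.raises(DataError):
        FusionWeights(w_x=np.array([-0.5, 1.5]), w_h=np.array([1.0]))


# -- fuse -------------------------------------------------------------


def naive_fuse(x, Hc, w_x, w_h, Px, Ph):
    T = Hc.shape[0]
    df = Px.shape[1]
    F = np.zeros((T, df))
    for t in range(T):
        for j in range(df):
            F[t, j] = (w_x * x) @ Px[:, j] + w_h[t] * (Hc[t] @ Ph[:, j])
    return F


def test_fuse_matches_loop_oracle():
    rng = np.random.default_rng(1)
    Dx, Dh, df, T = 4, 6, 3, 5
    x = rng.normal(size=Dx)
    Hc = rng.normal(size=(T, Dh))
    w_x = rng.random(Dx); w_x /= w_x.sum()
    w_h = rng.random(T); w_h /= w_h.sum()
    Px = rng.normal(size=(Dx, df))
    Ph = rng.normal(size=(Dh, df))
    weights = FusionWeights(w_x=w_x, w_h=w_h)
    F = fuse(x, Hc, weights, Px, Ph)
    assert np.allclose(F, naive_fuse(x, Hc, w_x, w_h, Px, Ph), rtol=1e-10)


def test_fuse_reduces_to_context_term_when_local_weight_is_zero():
    rng = np.random.default_rng(2)
    x = rng.normal(size=3)
    Hc = rng.normal(size=(4, 2))
    Px = rng.normal(size=(3, 2))
    Ph = rng.normal(size=(2, 2))
    zero_local = types.SimpleNamespace(
        w_x=np.zeros(3), w_h=np.full(4, 0.25)
    )
    F = fuse(x, Hc, zero_local, Px, Ph)
    assert np.allclose(F, 0.25 * (Hc @ Ph))


def test_fuse_single_timestep_is_single_row():
    rng = np.random.default_rng(3)
    weights = FusionWeights(w_x=np.array([1.0]), w_h=np.array([1.0]))
    F = fuse(rng.normal(size=1), rng.normal(size=(1, 2)),
             weights, rng.normal(size=(1, 3)), rng.normal(size=(2, 3)))
    assert F.shape == (1, 3)


def test_fusion_layer_width_mismatch_rejected():
    layer = FusionLayer(3, 4, 5, np.random.default_rng(0))
    with pytest.raises(DataError):
        layer.forward(
            np.ones((2, 7)), np.ones((2, 3, 4)), np.ones((2, 3), bool),
            FusionWeights.uniform(7, 3),
        )


# -- attention --------------------------------------------------------


def test_equal_scores_give_uniform_attention():
    F = np.ones((4, 2))
    q = np.zeros(2)
    alpha, c = attend(F, q, np.eye(2), np.zeros(2))
    assert np.allclose(alpha, 0.25)
    assert np.allclose(c, F[0])


def test_softmax_of_log_two_scores():
    """Scores (ln 2, 0) must give attention weights (2/3, 1/3)."""
    target = np.log(2.0)
    F = np.array([[np.arctanh(target)], [0.0]])  # tanh inverts to scores
    alpha, _ = attend(F, np.array([1.0]), np.array([[1.0]]), np.array([0.0]))
    assert np.allclose(alpha, [2 / 3, 1 / 3], atol=1e-9)


def test_single_position_gets_full_weight():
    F = np.array([[0.3, -1.2]])
    alpha, c = attend(F, np.ones(2), np.eye(2), np.zeros(2))
    assert np.allclose(alpha, [1.0])
    assert np.allclose(c, F[0])


def test_attention_weights_sum_to_one_and_shift_invariant():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=(3, 6))
    mask = rng.random((3, 6)) > 0.3
    mask[:, 0] = True
    alpha = masked_softmax(scores, mask)
    assert np.allclose(alpha.sum(axis=1), 1.0)
    assert np.allclose(alpha, masked_softmax(scores + 123.4, mask))
    assert np.all(alpha[~mask] == 0.0)


def test_attention_rejects_fully_masked_input():
    with pytest.raises(DegenerateInputError):
        attend(np.ones((2, 2)), np.ones(2), np.eye(2), np.zeros(2),
               mask=np.zeros(2, dtype=bool))


def test_attention_pooling_matches_functional_attend():
    rng = np.random.default_rng(5)
    pool = AttentionPooling(3, 4, rng)
    F = rng.normal(size=(2, 5, 3))
    mask = np.ones((2, 5), dtype=bool)
    mask[1, 3:] = False
    alpha, c, _ = pool.forward(F, mask)
    for b in range(2):
        a_ref, c_ref = attend(
            F[b], pool.params["q"], pool.params["Wa"], pool.params["ba"],
            mask=mask[b],
        )
        assert np.allclose(alpha[b], a_ref)
        assert np.allclose(c[b], c_ref)


def test_frozen_weights_make_pooling_deterministic():
    rng = np.random.default_rng(6)
    pool = AttentionPooling(2, 2, rng)
    F = rng.normal(size=(1, 4, 2))
    mask = np.ones((1, 4), dtype=bool)
    _, c1, _ = pool.forward(F, mask)
    _, c2, _ = pool.forward(F, mask)
    assert c1.tobytes() == c2.tobytes()
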