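"""BiLSTM channel: gate equations, oracle equivalence, symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igfuse import BiLstmChannel, EmbeddedSequence, LstmParams, bilstm_encode, lstm_step
from igfuse.errors import DataError, DegenerateInputError


def scalar_lstm_step(x, h_prev, c_prev, params):
    """Independent per-element evaluation of the gate equations."""
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    cat = np.concatenate([h_prev, x])
    w = params.weights
    i = sig(cat @ w["Wi"] + w["bi"])
    f = sig(cat @ w["Wf"] + w["bf"])
    g = np.tanh(cat @ w["WC"] + w["bC"])
    o = sig(cat @ w["Wo"] + w["bo"])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def _zero_params(hidden, input_dim):
    p = LstmParams.init(hidden, input_dim, np.random.default_rng(0))
    for k in p.weights:
        p.weights[k] = np.zeros_like(p.weights[k])
    return p


def test_all_zero_parameters_and_state_give_zero_output():
    p = _zero_params(3, 2)
    h, c = lstm_step(np.ones(2), np.zeros(3), np.zeros(3), p)
    assert np.allclose(h, 0.0) and np.allclose(c, 0.0)


def test_zero_weights_halve_previous_cell_state():
    """With zero weights the forget gate is sigmoid(0)=0.5, so the cell
    state update gives c_t = 0.5 * c_prev."""
    p = _zero_params(3, 2)
    v = np.array([0.4, -1.2, 2.0])
    h, c = lstm_step(np.ones(2), np.zeros(3), v, p)
    assert np.allclose(c, 0.5 * v)
    assert np.allclose(h, 0.5 * np.tanh(0.5 * v))


def test_lstm_step_matches_scalar_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        hidden = int(rng.integers(1, 9))
        d = int(rng.integers(1, 9))
        p = LstmParams.init(hidden, d, rng)
        x = rng.normal(size=d)
        h_prev = rng.normal(size=hidden)
        c_prev = rng.normal(size=hidden)
        h, c = lstm_step(x, h_prev, c_prev, p)
        h2, c2 = scalar_lstm_step(x, h_prev, c_prev, p)
        assert np.allclose(h, h2, rtol=1e-5)
        assert np.allclose(c, c2, rtol=1e-5)


def test_lstm_step_rejects_nan():
    p = _zero_params(2, 2)
    with pytest.raises(DataError):
        lstm_step(np.array([np.nan, 0.0]), np.zeros(2), np.zeros(2), p)


def _embedded(rows):
    rows = np.asarray(rows, float)
    return EmbeddedSequence(H=rows, mask=np.ones(rows.shape[0], dtype=bool))


def test_bilstm_single_timestep_concatenates_directions():
    rng = np.random.default_rng(6)
    fwd = LstmParams.init(3, 2, rng)
    bwd = LstmParams.init(3, 2, rng)
    x = rng.normal(size=(1, 2))
    out = bilstm_encode(_embedded(x), fwd, bwd)
    hf, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), fwd)
    hb, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), bwd)
    assert np.allclose(out[0], np.concatenate([hf, hb]))


def test_bilstm_output_width_at_default_hidden_size():
    rng = np.random.default_rng(7)
    fwd = LstmParams.init(128, 4, rng)
    bwd = LstmParams.init(128, 4, rng)
    out = bilstm_encode(_embedded(rng.normal(size=(3, 4))), fwd, bwd)
    assert out.shape == (3, 256)


def test_bilstm_matches_naive_recurrence_oracle():
    """The recurrence agrees with an independent scalar-loop oracle on
    random instances (T <= 10, hidden <= 8)."""
    rng = np.random.default_rng(8)
    for _ in range(50):
        T = int(rng.integers(1, 11))
        d = int(rng.integers(1, 6))
        hidden = int(rng.integers(1, 9))
        fwd = LstmParams.init(hidden, d, rng)
        bwd = LstmParams.init(hidden, d, rng)
        X = rng.normal(size=(T, d))
        out = bilstm_encode(_embedded(X), fwd, bwd)
        h = np.zeros(hidden); c = np.zeros(hidden)
        expect_f = []
        for t in range(T):
            h, c = scalar_lstm_step(X[t], h, c, fwd)
            expect_f.append(h)
        h = np.zeros(hidden); c = np.zeros(hidden)
        expect_b = [None] * T
        for t in range(T - 1, -1, -1):
            h, c = scalar_lstm_step(X[t], h, c, bwd)
            expect_b[t] = h
        expected = np.hstack([np.array(expect_f), np.array(expect_b)])
        assert np.allclose(out, expected, rtol=1e-5, atol=1e-8)


def test_reversing_input_swaps_direction_roles():
    rng = np.random.default_rng(9)
    fwd = LstmParams.init(4, 3, rng)
    bwd = LstmParams.init(4, 3, rng)
    X = rng.normal(size=(6, 3))
    out = bilstm_encode(_embedded(X), fwd, bwd)
    out_rev = bilstm_encode(_embedded(X[::-1]), bwd, fwd)
    # forward states on X == backward states on reversed X (and vice versa)
    assert np.allclose(out[:, :4], out_rev[::-1, 4:], rtol=1e-10)
    assert np.allclose(out[:, 4:], out_rev[::-1, :4], rtol=1e-10)


def test_empty_sequence_rejected():
    rng = np.random.default_rng(10)
    fwd = LstmParams.init(2, 2, rng)
    bwd = LstmParams.init(2, 2, rng)
    seq = EmbeddedSequence(H=np.zeros((2, 2)), mask=np.zeros(2, dtype=bool))
    with pytest.raises(DegenerateInputError):
        bilstm_encode(seq, fwd, bwd)


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_hidden_states_bounded_by_one(seed):
    """|h_t| <= 1 elementwise for any input (sigmoid x tanh bound)."""
    rng = np.random.default_rng(seed)
    fwd = LstmParams.init(3, 2, rng)
    bwd = LstmParams.init(3, 2, rng)
    X = rng.normal(scale=10.0, size=(5, 2))
    out = bilstm_encode(_embedded(X), fwd, bwd)
    assert np.all(np.abs(out) <= 1.0)


def test_batched_channel_matches_single_sequence_encoder():
    """The padded/masked batch implementation agrees with the
    single-sequence recurrence sample by sample."""
    rng = np.random.default_rng(11)
    channel = BiLstmChannel(3, 4, rng)
    lengths = [5, 2, 7]
    seqs = [rng.normal(size=(n, 3)) for n in lengths]
    T = max(lengths)
    H = np.zeros((3, T, 3))
    mask = np.zeros((3, T), dtype=bool)
    for b, s in enumerate(seqs):
        H[b, : len(s)] = s
        mask[b, : len(s)] = True
    Hc, _ = channel.forward(H, mask)
    for b, s in enumerate(seqs):
        single = bilstm_encode(_embedded(s), channel.fwd, channel.bwd)
        assert np.allclose(Hc[b, : len(s)], single, rtol=1e-10)
        assert np.allclose(Hc[b, len(s):], 0.0)  # masked rows are zero
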