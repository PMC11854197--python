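"""Context channel: bidirectional LSTM over the embedded sequence.

Each direction is a standard single-layer LSTM with independent
parameters.  Per timestep the gates are

    i_t = sigmoid(W_i [h_{t-1}; x_t] + b_i)        input gate
    f_t = sigmoid(W_f [h_{t-1}; x_t] + b_f)        forget gate
    g_t = tanh   (W_C [h_{t-1}; x_t] + b_C)        candidate cell
    o_t = sigmoid(W_o [h_{t-1}; x_t] + b_o)        output gate
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

from zero initial states.  The channel output at timestep t
concatenates the forward and backward hidden states, giving a
T x 2*hidden matrix; masked (padded) positions contribute zero rows.

The backward direction is realised by iterating timesteps in descending
order with the same mask gating, which on right-padded batches is
exactly a per-sample reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddedSequence
from .errors import DataError, DegenerateInputError

_GATES = ("i", "f", "C", "o")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LstmParams:
    """One direction's gate weights; each W_* is (hidden+input, hidden)."""

    hidden: int
    input_dim: int
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def init(
        cls, hidden: int, input_dim: int, rng: np.random.Generator
    ) -> "LstmParams":
        scale = 1.0 / np.sqrt(hidden + input_dim)
        weights = {}
        for g in _GATES:
            weights[f"W{g}"] = rng.normal(
                0.0, scale, size=(hidden + input_dim, hidden)
            )
            weights[f"b{g}"] = np.zeros(hidden)
        return cls(hidden=hidden, input_dim=input_dim, weights=weights)


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LstmParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns (h_t, c_t).

    Accepts single vectors or batched (B, dim) arrays.
    """
    x_t, h_prev, c_prev = (np.asarray(a, dtype=float) for a in (x_t, h_prev, c_prev))
    if np.isnan(x_t).any():
        raise DataError("NaN in LSTM input")
    cat = np.concatenate([h_prev, x_t], axis=-1)
    w = params.weights
    i = _sigmoid(cat @ w["Wi"] + w["bi"])
    f = _sigmoid(cat @ w["Wf"] + w["bf"])
    g = np.tanh(cat @ w["WC"] + w["bC"])
    o = _sigmoid(cat @ w["Wo"] + w["bo"])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class BiLstmChannel:
    """Batched bidirectional LSTM with manual BPTT."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.input_dim = input_dim
        self.fwd = LstmParams.init(hidden, input_dim, rng)
        self.bwd = LstmParams.init(hidden, input_dim, rng)

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden

    # -- forward ------------------------------------------------------

    def _run_direction(
        self, H: np.ndarray, mask: np.ndarray, params: LstmParams, reverse: bool
    ) -> tuple[np.ndarray, list[dict]]:
        B, T, _ = H.shape
        nh = self.hidden
        h = np.zeros((B, nh))
        c = np.zeros((B, nh))
        out = np.zeros((B, T, nh))
        steps: list[dict] = []
        order = range(T - 1, -1, -1) if reverse else range(T)
        w = params.weights
        for t in order:
            m = mask[:, t][:, None]  # (B,1)
            cat = np.concatenate([h, H[:, t]], axis=1)
            i = _sigmoid(cat @ w["Wi"] + w["bi"])
            f = _sigmoid(cat @ w["Wf"] + w["bf"])
            g = np.tanh(cat @ w["WC"] + w["bC"])
            o = _sigmoid(cat @ w["Wo"] + w["bo"])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            steps.append(
                {
                    "t": t, "m": m, "cat": cat, "i": i, "f": f, "g": g,
                    "o": o, "c_prev": c, "c_new": c_new, "tanh_c": tanh_c,
                }
            )
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            out[:, t] = h * m
        return out, steps

    def forward(
        self, H: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, dict]:
        """H: (B, T, d); mask: (B, T) boolean. Returns (Hc, cache) with
        Hc of shape (B, T, 2*hidden)."""
        if mask.sum(axis=1).min() < 1:
            raise DegenerateInputError("empty sequence in batch")
        mask_f = mask.astype(float)
        out_f, steps_f = self._run_direction(H, mask_f, self.fwd, reverse=False)
        out_b, steps_b = self._run_direction(H, mask_f, self.bwd, reverse=True)
        Hc = np.concatenate([out_f, out_b], axis=2)
        cache = {
            "H_shape": H.shape, "mask": mask_f,
            "steps_f": steps_f, "steps_b": steps_b,
        }
        return Hc, cache

    # -- backward -----------------------------------------------------

    def _backprop_direction(
        self,
        dOut: np.ndarray,
        steps: list[dict],
        params: LstmParams,
        dH: np.ndarray,
        grads: dict[str, np.ndarray],
        prefix: str,
    ) -> None:
        B = dOut.shape[0]
        nh = self.hidden
        w = params.weights
        dh_carry = np.zeros((B, nh))
        dc_carry = np.zeros((B, nh))
        for step in reversed(steps):
            t, m = step["t"], step["m"]
            # h after gating: h = m*h_new + (1-m)*h_prev; out[:,t] = h*m
            dh_total = dh_carry + dOut[:, t] * m
            dh_new = dh_total * m
            dh_prev = dh_total * (1.0 - m)
            dc_total = dc_carry
            dc_new = dc_total * m
            dc_prev_gate = dc_total * (1.0 - m)

            o, tanh_c = step["o"], step["tanh_c"]
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1.0 - tanh_c**2)
            i, f, g = step["i"], step["f"], step["g"]
            df = dc_new * step["c_prev"]
            di = dc_new * g
            dg = dc_new * i
            dc_prev = dc_new * f + dc_prev_gate

            dz = {
                "i": di * i * (1.0 - i),
                "f": df * f * (1.0 - f),
                "C": dg * (1.0 - g**2),
                "o": do * o * (1.0 - o),
            }
            cat = step["cat"]
            dcat = np.zeros_like(cat)
            for gate in _GATES:
                grads[f"{prefix}W{gate}"] += cat.T @ dz[gate]
                grads[f"{prefix}b{gate}"] += dz[gate].sum(axis=0)
                dcat += dz[gate] @ w[f"W{gate}"].T
            dh_carry = dh_prev + dcat[:, :nh]
            dH[:, t] += dcat[:, nh:]
            dc_carry = dc_prev

    def backward(
        self, dHc: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """dHc: (B, T, 2*hidden) -> (dH, gradient dict)."""
        B, T, d = cache["H_shape"]
        nh = self.hidden
        dH = np.zeros((B, T, d))
        grads = {
            f"{p}{n}": np.zeros_like(arr)
            for p, params in (("f_", self.fwd), ("b_", self.bwd))
            for n, arr in params.weights.items()
        }
        self._backprop_direction(
            dHc[:, :, :nh], cache["steps_f"], self.fwd, dH, grads, "f_"
        )
        self._backprop_direction(
            dHc[:, :, nh:], cache["steps_b"], self.bwd, dH, grads, "b_"
        )
        return dH, grads

    # -- parameter plumbing ------------------------------------------

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, p in (("f_", self.fwd), ("b_", self.bwd)):
            for name, arr in p.weights.items():
                out[prefix + name] = arr
        return out

    def set_params(self, flat: dict[str, np.ndarray]) -> None:
        for prefix, p in (("f_", self.fwd), ("b_", self.bwd)):
            for name in list(p.weights):
                p.weights[name] = flat[prefix + name]


def bilstm_encode(
    H: EmbeddedSequence,
    fwd: LstmParams,
    bwd: LstmParams,
) -> np.ndarray:
    """Encode one sequence; returns the T x 2*hidden context matrix.

    Runs the forward pass over t = 1..T and the backward pass over
    t = T..1, both from zero initial states, and concatenates the two
    direction states at each timestep.
    """
    rows = H.H[H.mask]
    T = rows.shape[0]
    if T == 0:
        raise DegenerateInputError("empty sequence")
    nh = fwd.hidden
    out = np.zeros((T, 2 * nh))
    h = np.zeros(nh)
    c = np.zeros(nh)
    for t in range(T):
        h, c = lstm_step(rows[t], h, c, fwd)
        out[t, :nh] = h
    h = np.zeros(nh)
    c = np.zeros(nh)
    for t in range(T - 1, -1, -1):
        h, c = lstm_step(rows[t], h, c, bwd)
        out[t, nh:] = h
    return out
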