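"""Dual-channel classifier: architecture, forward/backward, output head.

The network maps a padded batch of token-index sequences through

  1. composite embedding (token + segment + position tables),
  2. two parallel channels — multi-kernel CNN (local n-gram features x)
     and BiLSTM (per-timestep context H_c),
  3. the information-gain-weighted fusion layer and attention pooling
     producing the global vector c,
  4. an output head giving P(y=1 | c).

Two heads are available.  The default ``standard`` head is
linear -> ReLU -> linear -> sigmoid.  The ``literal`` head applies
sigmoid -> ReLU -> sigmoid to a single node; because its first sigmoid
already maps into (0,1), its final probability can never drop below
0.5, so it cannot separate classes at the 0.5 decision threshold — it
is kept selectable for architecture ablations only.

All gradients are computed analytically in NumPy; there is no autograd
dependency.  Information-gain fusion weights are constants during
backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel_context import BiLstmChannel
from .channel_local import ConvSpec, TextCNNChannel
from .errors import ConfigError, DataError, DegenerateInputError
from .ig_fusion import AttentionPooling, FusionLayer, FusionWeights
from .textprep import PAD_INDEX, Vocabulary

HEADS = ("standard", "literal")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 100-dimensional input
    vectors, 128 convolution filters for each of three kernel sizes
    (5, 7, 3), 128 LSTM units per direction, and a 256-wide fused
    representation.
    """

    embedding_dim: int = 100
    max_len: int = 128
    kernel_sizes: tuple[int, ...] = (5, 7, 3)
    filters_per_size: int = 128
    conv_bias: bool = True
    lstm_hidden: int = 128
    fused_dim: int = 256
    attn_dim: int = 64
    head: str = "standard"
    head_hidden: int = 64
    ig_bins: int = 10
    ig_eps: float = 1e-12
    ig_min_samples: int = 64

    def __post_init__(self) -> None:
        if self.head not in HEADS:
            raise ConfigError(f"head must be one of {HEADS}, got {self.head!r}")
        if min(
            self.embedding_dim, self.max_len, self.filters_per_size,
            self.lstm_hidden, self.fused_dim, self.attn_dim, self.head_hidden,
        ) < 1:
            raise ConfigError("all model dimensions must be >= 1")


@dataclass(frozen=True)
class Prediction:
    """A per-document prediction.

    ``label`` is 1 iff the probability strictly exceeds 0.5;
    ``entropy_bits`` is the Bernoulli entropy of the probability
    (base 2), the per-sample ingredient of the confidence score.
    """

    probability: float
    label: int
    entropy_bits: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    z = np.asarray(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bernoulli_entropy_bits(p: np.ndarray) -> np.ndarray:
    """H2(p) with the 0*log(0) := 0 convention; result in [0, 1] bits."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out


class DualChannelModel:
    """The assembled network with flat parameter access for training."""

    def __init__(self, vocab: Vocabulary, config: ModelConfig, seed: int = 0):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.embedding_dim
        self.emb = {
            "Et": rng.normal(0.0, 0.1, (vocab.total_size, d)),
            "Es": rng.normal(0.0, 0.1, (2, d)),
            "Ep": rng.normal(0.0, 0.1, (config.max_len, d)),
        }
        self.conv_spec = ConvSpec(
            kernel_sizes=config.kernel_sizes,
            filters_per_size=config.filters_per_size,
            bias=config.conv_bias,
        )
        self.cnn = TextCNNChannel(d, self.conv_spec, rng)
        self.lstm = BiLstmChannel(d, config.lstm_hidden, rng)
        self.fusion = FusionLayer(
            self.conv_spec.output_dim,
            self.lstm.output_dim,
            config.fused_dim,
            rng,
        )
        self.attention = AttentionPooling(config.fused_dim, config.attn_dim, rng)
        if config.head == "standard":
            self.head = {
                "W1": rng.normal(
                    0.0, 1.0 / np.sqrt(config.fused_dim),
                    (config.fused_dim, config.head_hidden),
                ),
                "b1": np.zeros(config.head_hidden),
                "w2": rng.normal(0.0, 1.0 / np.sqrt(config.head_hidden),
                                 config.head_hidden),
                "b2": np.zeros(1),
            }
        else:
            self.head = {
                "w1": rng.normal(0.0, 1.0 / np.sqrt(config.fused_dim),
                                 config.fused_dim),
                "b1": np.zeros(1),
            }
        self.fusion_weights = FusionWeights.uniform(
            self.conv_spec.output_dim, config.max_len
        )

    # -- parameter plumbing ------------------------------------------

    @property
    def params(self) -> dict[str, np.ndarray]:
        flat: dict[str, np.ndarray] = {}
        for name, arr in self.emb.items():
            flat[f"emb_{name}"] = arr
        for name, arr in self.cnn.params.items():
            flat[f"cnn_{name}"] = arr
        for name, arr in self.lstm.params.items():
            flat[f"lstm_{name}"] = arr
        for name, arr in self.fusion.params.items():
            flat[f"fus_{name}"] = arr
        for name, arr in self.attention.params.items():
            flat[f"att_{name}"] = arr
        for name, arr in self.head.items():
            flat[f"head_{name}"] = arr
        return flat

    def set_params(self, flat: dict[str, np.ndarray]) -> None:
        for name in list(self.emb):
            self.emb[name] = flat[f"emb_{name}"]
        for name in list(self.cnn.params):
            self.cnn.params[name] = flat[f"cnn_{name}"]
        self.lstm.set_params(
            {k[len("lstm_"):]: v for k, v in flat.items() if k.startswith("lstm_")}
        )
        for name in list(self.fusion.params):
            self.fusion.params[name] = flat[f"fus_{name}"]
        for name in list(self.attention.params):
            self.attention.params[name] = flat[f"att_{name}"]
        for name in list(self.head):
            self.head[name] = flat[f"head_{name}"]

    # -- batch preparation -------------------------------------------

    def pad_batch(
        self, token_index_lists: list[list[int]]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Truncate to max_len and right-pad to a common length.

        The padded length is at least the largest kernel size so the
        CNN channel always has one valid window.
        """
        if not token_index_lists:
            raise DegenerateInputError("empty batch")
        cfg = self.config
        clipped = [ids[: cfg.max_len] for ids in token_index_lists]
        if any(len(ids) == 0 for ids in clipped):
            raise DegenerateInputError("empty token sequence in batch")
        T = max(max(len(ids) for ids in clipped), max(cfg.kernel_sizes))
        B = len(clipped)
        ids = np.full((B, T), PAD_INDEX, dtype=int)
        mask = np.zeros((B, T), dtype=bool)
        for b, seq in enumerate(clipped):
            ids[b, : len(seq)] = seq
            mask[b, : len(seq)] = True
        return ids, mask

    # -- forward / backward ------------------------------------------

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> dict:
        B, T = ids.shape
        lengths = mask.sum(axis=1)
        mask_f = mask.astype(float)[:, :, None]
        H = (self.emb["Et"][ids] + self.emb["Es"][0] + self.emb["Ep"][:T]) * mask_f
        x, cnn_cache = self.cnn.forward(H, lengths)
        Hc, lstm_cache = self.lstm.forward(H, mask)
        F, fus_cache = self.fusion.forward(x, Hc, mask, self.fusion_weights)
        alpha, c, att_cache = self.attention.forward(F, mask)
        p, head_cache = self._head_forward(c)
        return {
            "ids": ids, "mask": mask, "H": H, "x": x, "Hc": Hc, "F": F,
            "alpha": alpha, "c": c, "p": p,
            "caches": (cnn_cache, lstm_cache, fus_cache, att_cache, head_cache),
        }

    def _head_forward(self, c: np.ndarray) -> tuple[np.ndarray, dict]:
        if self.config.head == "standard":
            a1 = c @ self.head["W1"] + self.head["b1"]
            r = np.maximum(a1, 0.0)
            logit = r @ self.head["w2"] + self.head["b2"][0]
            p = _sigmoid(logit)
            return p, {"c": c, "a1": a1, "r": r}
        z = _sigmoid(c @ self.head["w1"] + self.head["b1"][0])
        zp = np.maximum(z, 0.0)
        p = _sigmoid(zp)
        return p, {"c": c, "z": z}

    def _head_backward(
        self, dfinal: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """dfinal is dL/d(final pre-sigmoid activation) = (p - y)/B."""
        if self.config.head == "standard":
            r, a1, c = cache["r"], cache["a1"], cache["c"]
            grads = {
                "head_w2": r.T @ dfinal,
                "head_b2": np.array([dfinal.sum()]),
            }
            dr = dfinal[:, None] * self.head["w2"][None, :]
            da1 = dr * (a1 > 0)
            grads["head_W1"] = c.T @ da1
            grads["head_b1"] = da1.sum(axis=0)
            dc = da1 @ self.head["W1"].T
            return dc, grads
        z, c = cache["z"], cache["c"]
        dz = dfinal * (z > 0)
        dpre = dz * z * (1.0 - z)
        grads = {
            "head_w1": c.T @ dpre,
            "head_b1": np.array([dpre.sum()]),
        }
        dc = dpre[:, None] * self.head["w1"][None, :]
        return dc, grads

    def backward(self, out: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        """Mean binary cross-entropy gradients for the whole batch."""
        cnn_cache, lstm_cache, fus_cache, att_cache, head_cache = out["caches"]
        B = y.shape[0]
        dfinal = (out["p"] - y) / B
        dc, grads = self._head_backward(dfinal, head_cache)
        dF, att_grads = self.attention.backward(dc, att_cache)
        grads.update({f"att_{k}": v for k, v in att_grads.items()})
        dx, dHc, fus_grads = self.fusion.backward(dF, fus_cache)
        grads.update({f"fus_{k}": v for k, v in fus_grads.items()})
        dH_cnn, cnn_grads = self.cnn.backward(dx, cnn_cache)
        grads.update({f"cnn_{k}": v for k, v in cnn_grads.items()})
        dH_lstm, lstm_grads = self.lstm.backward(dHc, lstm_cache)
        grads.update({f"lstm_{k}": v for k, v in lstm_grads.items()})
        dH = (dH_cnn + dH_lstm) * out["mask"].astype(float)[:, :, None]
        dEt = np.zeros_like(self.emb["Et"])
        np.add.at(dEt, out["ids"], dH)
        grads["emb_Et"] = dEt
        dEs = np.zeros_like(self.emb["Es"])
        dEs[0] = dH.sum(axis=(0, 1))
        grads["emb_Es"] = dEs
        dEp = np.zeros_like(self.emb["Ep"])
        dEp[: dH.shape[1]] = dH.sum(axis=0)
        grads["emb_Ep"] = dEp
        return grads

    # -- inference ----------------------------------------------------

    def predict_proba(
        self, token_index_lists: list[list[int]], batch_size: int = 64
    ) -> np.ndarray:
        probs = np.empty(len(token_index_lists))
        for start in range(0, len(token_index_lists), batch_size):
            chunk = token_index_lists[start : start + batch_size]
            ids, mask = self.pad_batch(chunk)
            out = self.forward(ids, mask)
            probs[start : start + len(chunk)] = out["p"]
        return probs

    def classify(self, c: np.ndarray) -> Prediction:
        """Head-only classification of a single fused vector c."""
        c = np.asarray(c, dtype=float)
        if np.isnan(c).any():
            raise DataError("NaN in fused vector")
        p, _ = self._head_forward(c[None, :])
        p = float(p[0])
        return Prediction(
            probability=p,
            label=int(p > 0.5),
            entropy_bits=float(bernoulli_entropy_bits(np.array([p]))[0]),
        )


class Adam:
    """Adam optimizer over a flat parameter dict."""

    def __init__(
        self,
        param_names: list[str],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[str, np.ndarray] = {n: None for n in param_names}
        self.v: dict[str, np.ndarray] = {n: None for n in param_names}

    def step(
        self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]
    ) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if self.m[name] is None:
                self.m[name] = np.zeros_like(params[name])
                self.v[name] = np.zeros_like(params[name])
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            update = m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay:
                # decoupled weight decay (AdamW)
                update = update + self.weight_decay * params[name]
            params[name] -= self.lr * update


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
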