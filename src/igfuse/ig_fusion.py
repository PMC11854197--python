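"""Information-gain-weighted fusion of the two channels plus attention.

The fusion layer is the model's core mechanism.  Each local feature
dimension x_i and each context timestep h_t is scored by the
information gain between that feature and the binary label,

    IG(x) = H(x) - H(x | y),

estimated by quantile-binning the feature activations (B bins, base-2
logarithms, epsilon-smoothed).  The IG values are normalized into
fusion weights

    w_{x_i} = IG(x_i) / sum_i IG(x_i),
    w_{h_t} = IG(h_t) / sum_t IG(h_t),

which rescale the two feature sets before they are combined.  Both
channels are linearly projected to a common width d_f; the weighted
local vector is broadcast across timesteps and added to the weighted
per-timestep context rows, giving a fused sequence F of shape T x d_f.
A learnable-query attention then pools F into the global vector c:

    score_t = q^T tanh(W F_t + b),
    alpha   = softmax(score) over unmasked timesteps,
    c       = sum_t alpha_t F_t.

IG weights are treated as constants during backpropagation (no gradient
through the entropy estimate) and are refreshed once per epoch, then
frozen for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, DegenerateInputError, EstimationError

# --------------------------------------------------------------------------
# Information gain estimation
# --------------------------------------------------------------------------


def _mutual_information_bits(joint: np.ndarray, eps: float) -> float:
    """MI in bits from a contingency table of counts (rows x labels)."""
    total = joint.sum()
    if total == 0:
        return 0.0
    pj = joint / total
    pr = pj.sum(axis=1, keepdims=True)
    pc = pj.sum(axis=0, keepdims=True)
    mask = pj > 0
    # eps only guards the denominator; occupied cells have pr*pc >= pj/n
    mi = (pj[mask] * np.log2(pj[mask] / np.maximum((pr @ pc)[mask], eps))).sum()
    return max(float(mi), 0.0)


def quantile_bin(values: np.ndarray, bins: int) -> np.ndarray:
    """Discretize a scalar feature into at most ``bins`` quantile bins.

    Features with at most ``bins`` distinct values are binned by value
    (quantile edges collapse on heavily tied data and would otherwise
    merge distinct values into one bin).
    """
    values = np.asarray(values, dtype=float)
    uniq, inverse = np.unique(values, return_inverse=True)
    if uniq.size <= bins:
        return inverse
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, values, side="left")


def information_gain(
    values: np.ndarray,
    labels: np.ndarray,
    bins: int = 10,
    eps: float = 1e-12,
) -> float:
    """IG (in bits) between a scalar feature and binary labels.

    The feature is quantile-binned into at most ``bins`` bins; the
    result is H(bin) - H(bin | label), which by symmetry of mutual
    information equals H(label) - H(label | bin).  Constant labels give
    IG = 0 with a warning rather than an exception.
    """
    if bins < 2:
        raise ConfigError(f"bin count must be >= 2, got {bins}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise DataError("values and labels must be equal-length vectors")
    if values.size < 2:
        raise EstimationError("need at least 2 samples to estimate IG")
    if np.setdiff1d(labels, [0, 1]).size:
        raise DataError("labels must be binary {0,1}")
    if len(np.unique(labels)) < 2:
        warnings.warn("constant labels: information gain is 0", stacklevel=2)
        return 0.0
    binned = quantile_bin(values, bins)
    nb = int(binned.max()) + 1
    joint = np.zeros((nb, 2))
    np.add.at(joint, (binned, labels), 1.0)
    return _mutual_information_bits(joint, eps)


# --------------------------------------------------------------------------
# Fusion weights
# --------------------------------------------------------------------------


@dataclass
class FusionWeights:
    """Normalized IG shares over local dims (w_x) and timesteps (w_h)."""

    w_x: np.ndarray
    w_h: np.ndarray

    def __post_init__(self) -> None:
        self.w_x = np.asarray(self.w_x, dtype=float)
        self.w_h = np.asarray(self.w_h, dtype=float)
        for name, w in (("w_x", self.w_x), ("w_h", self.w_h)):
            if w.min() < 0 or abs(w.sum() - 1.0) > 1e-6:
                raise DataError(f"{name} must be nonnegative and sum to 1")

    @classmethod
    def uniform(cls, n_local: int, n_steps: int) -> "FusionWeights":
        return cls(
            w_x=np.full(n_local, 1.0 / n_local),
            w_h=np.full(n_steps, 1.0 / n_steps),
        )


def _normalize_ig(ig: np.ndarray) -> np.ndarray:
    total = ig.sum()
    if total <= 0:
        return np.full(ig.shape, 1.0 / ig.size)
    return ig / total


def compute_fusion_weights(
    x: np.ndarray,
    Hc: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 10,
    eps: float = 1e-12,
    min_samples: int = 64,
) -> FusionWeights:
    """Estimate fusion weights from a batch of channel activations.

    ``x``: (n, D_x) local features; ``Hc``: (n, T, D_h) context
    sequences; ``mask``: (n, T) validity.  w_x has one entry per local
    dimension; w_h one entry per timestep (IG averaged over the hidden
    dimensions at that timestep, computed over the samples for which
    the timestep is real).  If every IG is zero, weights fall back to
    uniform.
    """
    x = np.asarray(x, dtype=float)
    Hc = np.asarray(Hc, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = x.shape[0]
    if n < min_samples:
        raise EstimationError(
            f"need >= {min_samples} samples to estimate fusion weights, got {n}"
        )
    if mask is None:
        mask = np.ones(Hc.shape[:2], dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ig_x = np.array(
            [information_gain(x[:, i], labels, bins, eps) for i in range(x.shape[1])]
        )
        T = Hc.shape[1]
        ig_h = np.zeros(T)
        for t in range(T):
            sel = mask[:, t]
            if sel.sum() < 2 or len(np.unique(labels[sel])) < 2:
                continue
            igs = [
                information_gain(Hc[sel, t, d], labels[sel], bins, eps)
                for d in range(Hc.shape[2])
            ]
            ig_h[t] = float(np.mean(igs))
    return FusionWeights(w_x=_normalize_ig(ig_x), w_h=_normalize_ig(ig_h))


# --------------------------------------------------------------------------
# Fusion layer (batched, with gradients through the projections)
# --------------------------------------------------------------------------


def masked_softmax(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over the last axis restricted to unmasked entries.

    Uses max-subtraction stabilization; invariant under an additive
    shift of all scores.  Masked entries get weight 0.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if (~mask).all(axis=-1).any():
        raise DegenerateInputError("all positions masked")
    s = np.where(mask, scores, -np.inf)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


class FusionLayer:
    """Project both channels to a common width and combine them.

    F_t = P_x(w_x * x) + w_h[t] * P_h(h_t), masked rows zeroed.
    The IG weights are constants; only the projections are trainable.
    """

    def __init__(
        self,
        local_dim: int,
        context_dim: int,
        fused_dim: int,
        rng: np.random.Generator,
    ) -> None:
        self.local_dim = local_dim
        self.context_dim = context_dim
        self.fused_dim = fused_dim
        self.params = {
            "Px": rng.normal(0.0, 1.0 / np.sqrt(local_dim), (local_dim, fused_dim)),
            "Ph": rng.normal(0.0, 1.0 / np.sqrt(context_dim), (context_dim, fused_dim)),
        }

    def forward(
        self,
        x: np.ndarray,
        Hc: np.ndarray,
        mask: np.ndarray,
        weights: FusionWeights,
    ) -> tuple[np.ndarray, dict]:
        B, T, _ = Hc.shape
        if x.shape[1] != self.local_dim or Hc.shape[2] != self.context_dim:
            raise DataError(
                f"channel widths {x.shape[1]}/{Hc.shape[2]} do not match the "
                f"fusion projections {self.local_dim}/{self.context_dim}"
            )
        if weights.w_h.shape[0] < T:
            raise DataError(
                f"w_h covers {weights.w_h.shape[0]} timesteps, batch has {T}"
            )
        wh = weights.w_h[:T]
        xw = weights.w_x[None, :] * x  # (B, Dx)
        u = xw @ self.params["Px"]  # (B, df)
        V = Hc @ self.params["Ph"]  # (B, T, df)
        mask_f = mask.astype(float)[:, :, None]
        F = (u[:, None, :] + wh[None, :, None] * V) * mask_f
        cache = {"xw": xw, "Hc": Hc, "V": V, "wh": wh, "mask_f": mask_f,
                 "w_x": weights.w_x}
        return F, cache

    def backward(
        self, dF: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
        dF = dF * cache["mask_f"]
        du = dF.sum(axis=1)  # (B, df)
        dV = dF * cache["wh"][None, :, None]
        grads = {
            "Px": cache["xw"].T @ du,
            "Ph": np.einsum("btd,btf->df", cache["Hc"], dV),
        }
        dxw = du @ self.params["Px"].T
        dx = dxw * cache["w_x"][None, :]
        dHc = dV @ self.params["Ph"].T
        return dx, dHc, grads


class AttentionPooling:
    """Learnable-query attention over the fused sequence."""

    def __init__(self, fused_dim: int, attn_dim: int, rng: np.random.Generator):
        self.params = {
            "Wa": rng.normal(0.0, 1.0 / np.sqrt(fused_dim), (fused_dim, attn_dim)),
            "ba": np.zeros(attn_dim),
            "q": rng.normal(0.0, 1.0 / np.sqrt(attn_dim), attn_dim),
        }

    def forward(
        self, F: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        if mask.sum(axis=1).min() < 1:
            raise DegenerateInputError("all positions masked")
        M = F @ self.params["Wa"] + self.params["ba"]
        Tn = np.tanh(M)
        s = Tn @ self.params["q"]  # (B, T)
        alpha = masked_softmax(s, mask)
        c = np.einsum("bt,btd->bd", alpha, F)
        cache = {"F": F, "Tn": Tn, "alpha": alpha, "mask": mask}
        return alpha, c, cache

    def backward(
        self, dc: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        F, Tn, alpha = cache["F"], cache["Tn"], cache["alpha"]
        dalpha = np.einsum("bd,btd->bt", dc, F)
        dF = alpha[:, :, None] * dc[:, None, :]
        # softmax backward
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        ds = ds * cache["mask"]
        dTn = ds[:, :, None] * self.params["q"][None, None, :]
        dM = dTn * (1.0 - Tn**2)
        grads = {
            "Wa": np.einsum("btd,bta->da", F, dM),
            "ba": dM.sum(axis=(0, 1)),
            "q": (Tn * ds[:, :, None]).sum(axis=(0, 1)),
        }
        dF = dF + dM @ self.params["Wa"].T
        return dF, grads


# --------------------------------------------------------------------------
# Single-sequence functional forms (contract/oracle surface)
# --------------------------------------------------------------------------


def fuse(
    x: np.ndarray,
    Hc: np.ndarray,
    weights: FusionWeights,
    Px: np.ndarray,
    Ph: np.ndarray,
) -> np.ndarray:
    """Fused sequence for one sample: T x d_f."""
    x = np.asarray(x, dtype=float)
    Hc = np.asarray(Hc, dtype=float)
    T = Hc.shape[0]
    u = (weights.w_x * x) @ Px
    return u[None, :] + weights.w_h[:T, None] * (Hc @ Ph)


def attend(
    F: np.ndarray,
    q: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention over one fused sequence; returns (alpha, c)."""
    F = np.asarray(F, dtype=float)
    T = F.shape[0]
    if mask is None:
        mask = np.ones(T, dtype=bool)
    if mask.sum() < 1:
        raise DegenerateInputError("all positions masked")
    s = np.tanh(F @ W + b) @ q
    alpha = masked_softmax(s, mask)
    c = alpha @ F
    return alpha, c
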