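"""Local-feature channel: parallel multi-kernel 1-D convolutions.

Parallel convolution kernels of several window sizes slide over the
embedded token sequence ("valid" convolution, no padding), pass through
ReLU, are max-pooled over time per filter, and the pooled vectors are
concatenated in kernel order into one local feature vector x of width
``len(kernel_sizes) * filters_per_size``.

Default kernel sizes are (5, 7, 3): the first three entries of the
empirical priority order (5, 7, 3, 6, 4, 2) over window sizes 2-7, with
three sizes being the count at which multi-kernel models peak before
overfitting.  128 filters per size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddedSequence
from .errors import ConfigError, DegenerateInputError

DEFAULT_KERNEL_PRIORITY = (5, 7, 3, 6, 4, 2)


@dataclass(frozen=True)
class ConvSpec:
    """Multi-kernel convolution configuration."""

    kernel_sizes: tuple[int, ...] = (5, 7, 3)
    filters_per_size: int = 128
    bias: bool = True

    def __post_init__(self) -> None:
        if not self.kernel_sizes or any(k < 1 for k in self.kernel_sizes):
            raise ConfigError(
                f"kernel sizes must be >= 1, got {self.kernel_sizes}"
            )
        if self.filters_per_size < 1:
            raise ConfigError("filters_per_size must be >= 1")

    @property
    def output_dim(self) -> int:
        return len(self.kernel_sizes) * self.filters_per_size


def conv_map(H: np.ndarray | EmbeddedSequence, kernel: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution of one k x d kernel over a T x d sequence.

    Entry t of the result is the inner product of the kernel with the
    window of rows t..t+k-1; output length is T - k + 1.
    """
    if isinstance(H, EmbeddedSequence):
        H = H.H[H.mask]
    H = np.asarray(H, dtype=float)
    if H.ndim == 1:
        H = H[:, None]
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim == 1:
        kernel = kernel[:, None]
    k = kernel.shape[0]
    T = H.shape[0]
    if T < k:
        raise DegenerateInputError(
            f"sequence length {T} shorter than kernel size {k}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(H, (k,), axis=0)
    # windows: (T-k+1, d, k) -> inner product with kernel (k, d)
    return np.einsum("tdk,kd->t", windows, kernel)


class TextCNNChannel:
    """Batched multi-kernel convolution layer with manual gradients.

    Sequences shorter than the largest kernel are expected to arrive
    right-padded with masked zero rows; pooling only considers window
    positions that start on a real token.
    """

    def __init__(self, input_dim: int, spec: ConvSpec, rng: np.random.Generator):
        self.spec = spec
        self.input_dim = input_dim
        self.params: dict[str, np.ndarray] = {}
        for k in spec.kernel_sizes:
            scale = 1.0 / np.sqrt(k * input_dim)
            self.params[f"W{k}"] = rng.normal(
                0.0, scale, size=(k * input_dim, spec.filters_per_size)
            )
            self.params[f"b{k}"] = np.zeros(spec.filters_per_size)

    def forward(self, H: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, dict]:
        """H: (B, T, d) zero-padded; lengths: (B,). Returns (x, cache)."""
        B, T, d = H.shape
        if T < max(self.spec.kernel_sizes):
            raise DegenerateInputError(
                f"padded length {T} shorter than largest kernel "
                f"{max(self.spec.kernel_sizes)}"
            )
        if np.any(lengths < 1):
            raise DegenerateInputError("all positions masked in some sample")
        pooled_parts: list[np.ndarray] = []
        cache: dict = {"H_shape": H.shape, "per_kernel": {}}
        for k in self.spec.kernel_sizes:
            L = T - k + 1
            windows = np.lib.stride_tricks.sliding_window_view(H, (k,), axis=1)
            Xw = windows.transpose(0, 1, 3, 2).reshape(B, L, k * d)
            Z = Xw @ self.params[f"W{k}"]
            if self.spec.bias:
                Z = Z + self.params[f"b{k}"]
            A = np.maximum(Z, 0.0)
            # Valid windows lie fully inside the real sequence; sequences
            # shorter than k keep their single leading (zero-padded) window
            # so every sample pools over at least one position.  This makes
            # pooled features independent of how far the batch is padded.
            pos = np.arange(L)[None, :]
            lens = lengths[:, None]
            valid = (pos <= lens - k) | ((lens < k) & (pos == 0))  # (B, L)
            A_masked = np.where(valid[:, :, None], A, -np.inf)
            argmax = A_masked.argmax(axis=1)  # (B, F)
            pooled = np.take_along_axis(A_masked, argmax[:, None, :], axis=1)[
                :, 0, :
            ]
            pooled_parts.append(pooled)
            cache["per_kernel"][k] = {"Xw": Xw, "Z": Z, "argmax": argmax, "L": L}
        x = np.concatenate(pooled_parts, axis=1)
        return x, cache

    def backward(
        self, dx: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """dx: (B, K*F) -> (dH, param grads)."""
        B, T, d = cache["H_shape"]
        F = self.spec.filters_per_size
        dH = np.zeros((B, T, d))
        grads: dict[str, np.ndarray] = {}
        for i, k in enumerate(self.spec.kernel_sizes):
            kc = cache["per_kernel"][k]
            L = kc["L"]
            dpool = dx[:, i * F : (i + 1) * F]  # (B, F)
            dA = np.zeros((B, L, F))
            np.put_along_axis(dA, kc["argmax"][:, None, :], dpool[:, None, :], axis=1)
            dZ = dA * (kc["Z"] > 0)
            grads[f"W{k}"] = np.einsum("blk,blf->kf", kc["Xw"], dZ)
            if self.spec.bias:
                grads[f"b{k}"] = dZ.sum(axis=(0, 1))
            dXw = dZ @ self.params[f"W{k}"].T  # (B, L, k*d)
            dXw = dXw.reshape(B, L, k, d)
            for j in range(k):
                dH[:, j : j + L, :] += dXw[:, :, j, :]
        return dH, grads


def extract_local(
    H: EmbeddedSequence, spec: ConvSpec, channel: TextCNNChannel | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-sequence local feature vector x (ReLU + max-pool + concat)."""
    if channel is None:
        channel = TextCNNChannel(
            H.H.shape[1], spec, rng or np.random.default_rng(0)
        )
    T_pad = max(H.H.shape[0], max(spec.kernel_sizes))
    Hp = np.zeros((1, T_pad, H.H.shape[1]))
    n = int(H.mask.sum())
    if n == 0:
        raise DegenerateInputError("all positions masked")
    Hp[0, :n] = H.H[H.mask]
    x, _ = channel.forward(Hp, np.array([n]))
    return x[0]
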