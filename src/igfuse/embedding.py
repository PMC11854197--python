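"""Token-sequence embedding: composite (token+segment+position) encoder.

Each token index is mapped to a d-dimensional vector as the elementwise
sum of three tables — token embeddings ``E_t``, segment embeddings
``E_s`` and position embeddings ``E_p`` — following the Transformer
input convention.  Microblogs are single sentences, so the segment id
is 0 throughout.

A contextual-language-model adapter can be registered under the name
``"bert-adapter"`` behind the same contract; requesting it without a
registered backend raises :class:`~igfuse.errors.CapabilityError`
rather than silently falling back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .errors import CapabilityError, ConfigError, DataError


@dataclass(frozen=True)
class EmbeddingConfig:
    """Encoder configuration.

    ``dimension`` is the embedding width d (default 100, matching the
    input-vector width used throughout the model); ``max_len`` is the
    truncation length for long posts.
    """

    dimension: int = 100
    max_len: int = 128
    encoder: str = "composite"

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ConfigError("embedding dimension must be >= 1")
        if self.max_len < 1:
            raise ConfigError("max_len must be >= 1")


@dataclass
class EmbeddedSequence:
    """A T x d matrix of token vectors plus a validity mask.

    ``mask[t]`` is False for padded positions; downstream sums over
    timesteps must exclude masked rows.
    """

    H: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.H.ndim != 2 or self.mask.shape != (self.H.shape[0],):
            raise DataError("H must be T x d with a length-T mask")

    @property
    def length(self) -> int:
        return int(self.mask.sum())


def composite_embed(
    token_indices: Sequence[int],
    E_t: np.ndarray,
    E_s: np.ndarray,
    E_p: np.ndarray,
    segment_ids: Sequence[int] | None = None,
) -> EmbeddedSequence:
    """Sum token, segment and position table rows for each position.

    Row t of the result is ``E_t[token_t] + E_s[segment_t] + E_p[t]``.
    Single-sentence input uses segment id 0 for every position.
    """
    E_t, E_s, E_p = (np.asarray(a, dtype=float) for a in (E_t, E_s, E_p))
    idx = np.asarray(token_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= E_t.shape[0]):
        raise DataError(
            f"token index out of range [0, {E_t.shape[0]}) : {idx.tolist()}"
        )
    T = idx.shape[0]
    if T > E_p.shape[0]:
        raise DataError(
            f"sequence length {T} exceeds position table size {E_p.shape[0]}"
        )
    seg = (
        np.zeros(T, dtype=int)
        if segment_ids is None
        else np.asarray(segment_ids, dtype=int)
    )
    if seg.size and (seg.min() < 0 or seg.max() >= E_s.shape[0]):
        raise DataError("segment index out of range")
    H = E_t[idx] + E_s[seg] + E_p[:T]
    return EmbeddedSequence(H=H, mask=np.ones(T, dtype=bool))


class Encoder(Protocol):
    def __call__(self, token_indices: Sequence[int]) -> EmbeddedSequence: ...


class CompositeEncoder:
    """Trainable composite embedding with seeded small-random tables."""

    def __init__(
        self,
        vocab_size: int,
        config: EmbeddingConfig = EmbeddingConfig(),
        n_segments: int = 2,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        d = config.dimension
        self.config = config
        self.E_t = rng.normal(0.0, 0.1, size=(vocab_size, d))
        self.E_s = rng.normal(0.0, 0.1, size=(n_segments, d))
        self.E_p = rng.normal(0.0, 0.1, size=(config.max_len, d))

    def __call__(self, token_indices: Sequence[int]) -> EmbeddedSequence:
        idx = list(token_indices)[: self.config.max_len]
        return composite_embed(idx, self.E_t, self.E_s, self.E_p)


EncoderFactory = Callable[..., Encoder]

_ENCODERS: dict[str, EncoderFactory | None] = {
    "composite": CompositeEncoder,
    # Seam for a pretrained contextual encoder; no backend ships with the
    # package, so requesting it raises CapabilityError until one is
    # registered via register_encoder().
    "bert-adapter": None,
}


def register_encoder(name: str, factory: EncoderFactory) -> None:
    _ENCODERS[name] = factory


def make_encoder(name: str, **kwargs) -> Encoder:
    if name not in _ENCODERS:
        raise ConfigError(
            f"unknown encoder {name!r}; registered: {sorted(_ENCODERS)}"
        )
    factory = _ENCODERS[name]
    if factory is None:
        raise CapabilityError(
            f"encoder {name!r} has no registered backend; install and "
            "register one with register_encoder()"
        )
    return factory(**kwargs)


def encode(token_indices: Sequence[int], encoder: Encoder) -> EmbeddedSequence:
    """Encode a token-index sequence with a prepared encoder instance."""
    out = encoder(token_indices)
    if np.isnan(out.H).any():
        raise DataError("encoder produced NaN embeddings")
    return out
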