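"""Training loop, stratified split, model persistence and inference.

Training follows the standard recipe for this architecture: stratified
80/20 train/test split, mini-batch Adam on binary cross-entropy, and a
refresh of the information-gain fusion weights at the start of every
epoch (estimated on a fixed-size reference sample of the training
split, then held constant for the epoch's gradient steps and frozen
for inference).

All randomness — split, parameter initialization, shuffling — derives
from the single seed in :class:`TrainConfig`, so identical config and
seed reproduce identical weights and predictions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import ConfigError, DataError, EstimationError, TrainingError
from .ig_fusion import FusionWeights, compute_fusion_weights
from .model import (
    Adam,
    DualChannelModel,
    ModelConfig,
    Prediction,
    bce_loss,
    bernoulli_entropy_bits,
)
from .textprep import CleanDocument, Vocabulary, build_vocab


def _savez_deterministic(path: Path, arrays: dict[str, np.ndarray]) -> None:
    """npz writer with fixed zip metadata so identical arrays give
    byte-identical files across runs (np.savez embeds timestamps)."""
    import io
    import zipfile

    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the seed drives every random choice."""

    seed: int
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    test_fraction: float = 0.2
    vocab_size: int = 5000
    threshold: float = 0.5
    weight_decay: float = 0.0
    ig_sample: int = 512

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0,1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


@dataclass
class TrainedModel:
    """A frozen model plus everything needed to reuse it."""

    model: DualChannelModel
    vocab: Vocabulary
    model_config: ModelConfig
    train_config: TrainConfig
    history: list[dict]
    test_doc_ids: list[str]

    def predict_docs(self, docs: list[CleanDocument]) -> tuple[list[Prediction], list[str]]:
        """Predict kept documents; returns (predictions, dropped ids)."""
        kept = [d for d in docs if d.kept]
        dropped = [d.doc_id for d in docs if not d.kept]
        if not kept:
            return [], dropped
        encoded = [self.vocab.encode(d.tokens) for d in kept]
        probs = self.model.predict_proba(encoded)
        ent = bernoulli_entropy_bits(probs)
        preds = [
            Prediction(
                probability=float(p),
                label=int(p > self.train_config.threshold),
                entropy_bits=float(h),
            )
            for p, h in zip(probs, ent)
        ]
        return preds, dropped

    # -- persistence --------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        arrays = dict(self.model.params)
        arrays["fusion_w_x"] = self.model.fusion_weights.w_x
        arrays["fusion_w_h"] = self.model.fusion_weights.w_h
        _savez_deterministic(model_dir / "weights.npz", arrays)
        (model_dir / "vocab.json").write_text(
            self.vocab.to_json(), encoding="utf-8"
        )
        meta = {
            "model_config": _config_dict(self.model_config),
            "train_config": asdict(self.train_config),
            "history": self.history,
            "test_doc_ids": self.test_doc_ids,
        }
        (model_dir / "meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "meta.json").read_text(encoding="utf-8"))
        vocab = Vocabulary.from_json(
            (model_dir / "vocab.json").read_text(encoding="utf-8")
        )
        mc = meta["model_config"]
        mc["kernel_sizes"] = tuple(mc["kernel_sizes"])
        model_config = ModelConfig(**mc)
        train_config = TrainConfig(**meta["train_config"])
        model = DualChannelModel(vocab, model_config, seed=train_config.seed)
        with np.load(model_dir / "weights.npz") as payload:
            flat = {k: payload[k] for k in payload.files}
        model.fusion_weights = FusionWeights(
            w_x=flat.pop("fusion_w_x"), w_h=flat.pop("fusion_w_h")
        )
        expected = set(model.params)
        if set(flat) != expected:
            raise DataError(
                "weight file does not match the model architecture "
                f"(missing {sorted(expected - set(flat))[:3]}...)"
            )
        model.set_params(flat)
        return cls(
            model=model,
            vocab=vocab,
            model_config=model_config,
            train_config=train_config,
            history=meta["history"],
            test_doc_ids=meta["test_doc_ids"],
        )


def _config_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    d["kernel_sizes"] = list(d["kernel_sizes"])
    return d


def stratified_split(
    docs: list[CleanDocument], test_fraction: float, seed: int
) -> tuple[list[CleanDocument], list[CleanDocument]]:
    """Stratified train/test split over kept, labeled documents."""
    labels = [d.label for d in docs]
    if any(lab is None for lab in labels):
        raise DataError("all documents must be labeled for training")
    if len(set(labels)) < 2:
        raise TrainingError("training corpus must contain both classes")
    train_docs, test_docs = train_test_split(
        docs,
        test_size=test_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return list(train_docs), list(test_docs)


def _refresh_fusion_weights(
    model: DualChannelModel,
    encoded: list[list[int]],
    labels: np.ndarray,
    sample: int,
) -> None:
    cfg = model.config
    n = min(sample, len(encoded))
    ids, mask = model.pad_batch(encoded[:n])
    out = model.forward(ids, mask)
    try:
        w = compute_fusion_weights(
            out["x"],
            out["Hc"],
            labels[:n],
            mask=mask,
            bins=cfg.ig_bins,
            eps=cfg.ig_eps,
            min_samples=cfg.ig_min_samples,
        )
    except EstimationError:
        # Not enough reference samples: keep current (initially uniform).
        return
    # w_h estimated on the padded batch length; embed into max_len.
    w_h = np.zeros(cfg.max_len)
    w_h[: w.w_h.shape[0]] = w.w_h
    model.fusion_weights = FusionWeights(w_x=w.w_x, w_h=w_h)


def train(
    docs: list[CleanDocument],
    train_config: TrainConfig,
    model_config: ModelConfig = ModelConfig(),
) -> TrainedModel:
    """Train the dual-channel model on preprocessed documents.

    Only kept documents participate.  The vocabulary is built from the
    training split alone.  Returns the frozen model together with the
    per-epoch loss history.
    """
    kept = [d for d in docs if d.kept]
    if not kept:
        raise TrainingError("no documents survived preprocessing")
    train_docs, test_docs = stratified_split(
        kept, train_config.test_fraction, train_config.seed
    )
    vocab = build_vocab(
        (d.tokens for d in train_docs), n=train_config.vocab_size
    )
    model = DualChannelModel(vocab, model_config, seed=train_config.seed)

    enc_train = [vocab.encode(d.tokens) for d in train_docs]
    y_train = np.array([d.label for d in train_docs], dtype=float)
    optimizer = Adam(
        list(model.params),
        lr=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
    )
    rng = np.random.default_rng(train_config.seed + 1)
    history: list[dict] = []
    params = model.params
    for epoch in range(train_config.epochs):
        _refresh_fusion_weights(
            model, enc_train, y_train, train_config.ig_sample
        )
        order = rng.permutation(len(enc_train))
        losses = []
        for start in range(0, len(order), train_config.batch_size):
            sel = order[start : start + train_config.batch_size]
            ids, mask = model.pad_batch([enc_train[i] for i in sel])
            out = model.forward(ids, mask)
            losses.append(bce_loss(out["p"], y_train[sel]))
            grads = model.backward(out, y_train[sel])
            optimizer.step(params, grads)
        history.append({"epoch": epoch + 1, "train_loss": float(np.mean(losses))})
    # Final weight refresh so frozen fusion weights reflect the trained model.
    _refresh_fusion_weights(
        model, enc_train, y_train, train_config.ig_sample
    )
    return TrainedModel(
        model=model,
        vocab=vocab,
        model_config=model_config,
        train_config=train_config,
        history=history,
        test_doc_ids=[d.doc_id for d in test_docs],
    )


def predictions_to_records(
    docs: list[CleanDocument], preds: list[Prediction]
) -> list[dict]:
    kept = [d for d in docs if d.kept]
    return [
        {
            "id": d.doc_id,
            "probability": p.probability,
            "label": p.label,
            "entropy_bits": p.entropy_bits,
        }
        for d, p in zip(kept, preds)
    ]
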