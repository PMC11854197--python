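"""YAML configuration schema and run manifests.

One YAML file configures the whole pipeline, with sections ``prep``,
``embedding``, ``cnn``, ``rnn``, ``fusion``, ``train`` and ``eval``; any
omitted key falls back to its default.  All randomness flows from the
single top-level ``seed``.

Every training/evaluation run writes a manifest recording the config
snapshot, seed, package version and SHA-256 digests of its input and
output files, so a rerun can be checked for bit-identical artifacts.
Wall-clock timings are deliberately logged to stderr rather than
stored in the manifest, keeping manifests reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import ModelConfig
from .train import TrainConfig

PACKAGE_VERSION = "0.1.0"

DEFAULTS: dict = {
    "seed": 0,
    "prep": {"min_chars": 5, "segmenter": "whitespace"},
    "embedding": {"dimension": 100, "max_len": 128, "encoder": "composite"},
    "cnn": {"kernel_sizes": [5, 7, 3], "filters": 128, "bias": True},
    "rnn": {"hidden": 128},
    "fusion": {
        "bins": 10,
        "epsilon": 1.0e-12,
        "min_samples": 64,
        "fused_dim": 256,
        "attn_dim": 64,
        "weight_refresh": "per-epoch",
    },
    "train": {
        "epochs": 10,
        "batch_size": 32,
        "learning_rate": 1.0e-3,
        "weight_decay": 0.0,
        "test_fraction": 0.2,
        "vocab_size": 5000,
        "threshold": 0.5,
        "ig_sample": 512,
        "head": "standard",
        "head_hidden": 64,
    },
    "eval": {"percent": True},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where}: expected a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _merge(DEFAULTS, raw)


def model_config_from(cfg: dict) -> ModelConfig:
    return ModelConfig(
        embedding_dim=int(cfg["embedding"]["dimension"]),
        max_len=int(cfg["embedding"]["max_len"]),
        kernel_sizes=tuple(int(k) for k in cfg["cnn"]["kernel_sizes"]),
        filters_per_size=int(cfg["cnn"]["filters"]),
        conv_bias=bool(cfg["cnn"]["bias"]),
        lstm_hidden=int(cfg["rnn"]["hidden"]),
        fused_dim=int(cfg["fusion"]["fused_dim"]),
        attn_dim=int(cfg["fusion"]["attn_dim"]),
        head=str(cfg["train"]["head"]),
        head_hidden=int(cfg["train"]["head_hidden"]),
        ig_bins=int(cfg["fusion"]["bins"]),
        ig_eps=float(cfg["fusion"]["epsilon"]),
        ig_min_samples=int(cfg["fusion"]["min_samples"]),
    )


def train_config_from(cfg: dict) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(
        seed=int(cfg["seed"]),
        epochs=int(t["epochs"]),
        batch_size=int(t["batch_size"]),
        learning_rate=float(t["learning_rate"]),
        weight_decay=float(t["weight_decay"]),
        test_fraction=float(t["test_fraction"]),
        vocab_size=int(t["vocab_size"]),
        threshold=float(t["threshold"]),
        ig_sample=int(t["ig_sample"]),
    )


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    cfg: dict,
    inputs: list[str | Path],
    outputs: list[str | Path],
) -> dict:
    base = Path(path).resolve().parent

    def _rel(p: str | Path) -> str:
        # paths stored relative to the manifest so reruns in different
        # directories still produce byte-identical manifests
        try:
            return str(Path(p).resolve().relative_to(base))
        except ValueError:
            return Path(p).name

    manifest = {
        "command": command,
        "package_version": PACKAGE_VERSION,
        "seed": cfg.get("seed"),
        "config": cfg,
        "inputs": {_rel(p): file_digest(p) for p in inputs if Path(p).is_file()},
        "outputs": {_rel(p): file_digest(p) for p in outputs if Path(p).is_file()},
    }
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
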