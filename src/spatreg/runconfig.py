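"""YAML run configuration.

A run config has up to three blocks::

    model: {input_shape: [48, 48, 32], initial_filters: 4, depth: 3, latent_dim: 32}
    train: {epochs: 30, learning_rate: 1.0e-3, seed: 0, split_seed: 0}
    loss:  {kind: edge, lambda1: 1.0, lambda2: 0.1, lambda3: 0.1, tau_mm: 3.0, dmax_mm: 40.0}

Missing keys fall back to the full-scale defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .core import ValidationError
from .network import ModelConfig
from .training import TrainConfig

__all__ = ["load_run_config"]

_LOSS_KEY_MAP = {"kind": "loss_kind", "lambda1": "lambda1", "lambda2": "lambda2",
                 "lambda3": "lambda3", "tau_mm": "tau_mm", "dmax_mm": "d_max_mm"}


def load_run_config(path: str | Path) -> tuple[ModelConfig, TrainConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_kwargs = dict(raw.get("model") or {})
    if "input_shape" in model_kwargs:
        model_kwargs["input_shape"] = tuple(model_kwargs["input_shape"])
    train_kwargs = dict(raw.get("train") or {})
    for key, dest in _LOSS_KEY_MAP.items():
        if key in (raw.get("loss") or {}):
            train_kwargs[dest] = raw["loss"][key]
    try:
        return ModelConfig(**model_kwargs), TrainConfig(**train_kwargs)
    except TypeError as exc:
        raise ValidationError(f"bad run config {path}: {exc}") from exc
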