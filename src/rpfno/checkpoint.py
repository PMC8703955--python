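"""Single-archive checkpoints: weights + configs + normalizer + seed.

A checkpoint is a ``.npz`` archive holding every parameter array under
``param_<name>`` plus a JSON metadata blob (model kind, architecture
config, frame normalizer, training seed and optionally the encoding
config).  Loading a checkpoint fully determines inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .encoding import EncodingConfig
from .nets import (
    FNOConfig,
    FNOForecaster,
    CNNConfig,
    CNNForecaster,
    LSTMDecoderNet,
    TwoLayerClassifier,
)


def save_checkpoint(path, model, encoding: EncodingConfig | None = None,
                    extra: dict | None = None) -> None:
    kind = model.kind
    if kind in ("fno", "cnn"):
        config = asdict(model.config)
    elif kind == "lstm_decoder":
        config = {
            "input_dim": model.input_dim,
            "hidden": model.hidden,
            "head_hidden": model.head_hidden,
            "out_dim": model.out_dim,
        }
    elif kind == "classifier":
        config = {
            "input_dim": model.input_dim,
            "hidden": model.hidden,
            "n_classes": model.n_classes,
        }
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    meta = {
        "kind": kind,
        "config": config,
        "scale": float(model.scale),
        "seed": int(getattr(model, "seed", 0)),
        "encoding": asdict(encoding) if encoding is not None else None,
        "extra": extra or {},
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    np.savez_compressed(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_checkpoint(path):
    """Rebuild the model; returns ``(model, encoding_config_or_None)``."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(archive["meta"].item().decode())
        params = {
            k[len("param_") :]: archive[k] for k in archive.files if k.startswith("param_")
        }
    kind, config, seed = meta["kind"], meta["config"], meta["seed"]
    if kind == "fno":
        config["width"] = int(config["width"])
        model = FNOForecaster(FNOConfig(**config), seed=seed)
    elif kind == "cnn":
        config["hidden"] = tuple(config["hidden"])
        model = CNNForecaster(CNNConfig(**config), seed=seed)
    elif kind == "lstm_decoder":
        model = LSTMDecoderNet(seed=seed, **config)
    elif kind == "classifier":
        model = TwoLayerClassifier(seed=seed, **config)
    else:
        raise ValueError(f"unknown model kind {kind!r} in checkpoint")
    for k, v in params.items():
        if k not in model.params or model.params[k].shape != v.shape:
            raise ValueError(f"checkpoint parameter {k!r} does not fit the model")
        model.params[k] = v.astype(model.params[k].dtype)
    model.scale = float(meta["scale"])
    model.checkpoint_extra = meta.get("extra", {})
    enc = meta.get("encoding")
    return model, (EncodingConfig(**enc) if enc else None)
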