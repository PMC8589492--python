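"""Model checkpoints: parameter arrays plus the embedded config.

Stored as ``.npz`` with the config serialized to a JSON string, so a
checkpoint is self-describing and can be rebuilt without the original
config file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .backbone import BackboneConfig, ResNeXtBackbone
from .errors import ValidationError
from .model import GDYNet, GDYNetConfig, InceptionSpec

__all__ = ["save_model", "load_model"]


def _config_dict(model) -> dict:
    cfg = dataclasses.asdict(model.cfg)
    cfg["__kind__"] = type(model).__name__
    return cfg


def save_model(model, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["__config__"] = np.frombuffer(
        json.dumps(_config_dict(model)).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_model(path: str | Path):
    path = Path(path)
    if not path.is_file():
        raise ValidationError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    kind = cfg.pop("__kind__")
    if kind == "GDYNet":
        cfg["inception"] = InceptionSpec(**cfg["inception"])
        model = GDYNet(GDYNetConfig(**cfg))
    elif kind == "ResNeXtBackbone":
        model = ResNeXtBackbone(BackboneConfig(**cfg))
    else:
        raise ValidationError(f"unknown checkpoint kind {kind!r}")
    model.load_state_dict(state)
    return model
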