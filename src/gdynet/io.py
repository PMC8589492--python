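"""Reading and writing images, masks, manifests, configs, and reports.

Conventions (used consistently by every module):

* pixel coordinates are 0-based, row-major; bounding boxes are half-open
  ``(row0, row1, col0, col1)``;
* images are float arrays in [0, 1]; stored as 8-bit PNG;
* masks are {0, 1} ``uint8`` in memory; stored as {0, 255} single-channel
  8-bit PNG for viewer compatibility; loading binarizes at pixel > 127;
* probability maps are stored as 16-bit PNG scaled by 65535, with a JSON
  sidecar recording the scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import ValidationError

__all__ = ["ManifestRow", "DatasetManifest", "read_manifest",
           "write_manifest", "load_image", "save_image", "load_mask",
           "save_mask", "save_prob_map", "load_prob_map", "load_config",
           "dump_config", "write_json_report", "read_json_report"]

_REQUIRED_COLUMNS = ("image_path", "disc_mask_path", "label", "split")


@dataclass
class ManifestRow:
    image_path: str
    disc_mask_path: str | None = None
    label: int | None = None
    split: str = "train"
    cdr: float | None = None


@dataclass
class DatasetManifest:
    rows: list[ManifestRow]

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.rows if r.split == split])

    def validate(self, strict: bool = False) -> None:
        paths = [r.image_path for r in self.rows]
        if len(set(paths)) != len(paths):
            raise ValidationError("duplicate image paths in manifest")
        if strict:
            problems = []
            for i, r in enumerate(self.rows):
                if not Path(r.image_path).is_file():
                    problems.append(f"row {i}: missing image {r.image_path}")
                if r.disc_mask_path and not Path(r.disc_mask_path).is_file():
                    problems.append(
                        f"row {i}: missing mask {r.disc_mask_path}")
            if problems:
                raise ValidationError("; ".join(problems))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for r in manifest.rows:
        records.append({
            "image_path": r.image_path,
            "disc_mask_path": r.disc_mask_path if r.disc_mask_path else "",
            "label": "" if r.label is None else int(r.label),
            "split": r.split,
            "cdr": "" if r.cdr is None else r.cdr,
        })
    pd.DataFrame.from_records(
        records, columns=list(_REQUIRED_COLUMNS) + ["cdr"]
    ).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, strict: bool = False) -> DatasetManifest:
    path = Path(path)
    if not path.is_file():
        raise ValidationError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"image_path": str, "disc_mask_path": str,
                                  "split": str}, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"manifest {path} is missing required columns: {missing}")
    rows = []
    for rec in df.to_dict("records"):
        label = rec.get("label", "")
        cdr = rec.get("cdr", "")
        rows.append(ManifestRow(
            image_path=rec["image_path"],
            disc_mask_path=rec["disc_mask_path"] or None,
            label=None if label in ("", None) else int(float(label)),
            split=rec["split"] or "train",
            cdr=None if cdr in ("", None) else float(cdr)))
    manifest = DatasetManifest(rows)
    manifest.validate(strict=strict)
    return manifest


# -- raster I/O -----------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Load an image as (H, W, 3) float in [0, 1]."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot decode image {path}: {exc}") from exc
    return arr / 255.0


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask: pixels > 127 map to 1."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot decode mask {path}: {exc}") from exc
    return (arr > 127).astype(np.uint8)


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)
    return path


def save_prob_map(prob: np.ndarray, path: str | Path) -> Path:
    """Persist a probability map as 16-bit PNG + JSON scale sidecar."""
    path = Path(path)
    arr = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 65535.0).round().astype(np.uint16)).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"scale": 65535, "dtype": "uint16"}))
    return path

def load_prob_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    scale = 65535.0
    if sidecar.is_file():
        scale = float(json.loads(sidecar.read_text()).get("scale", 65535))
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64)
    return arr / scale


# -- config and report I/O ------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} does not contain a mapping")
    return data


def dump_config(cfg, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, default=_jsonify))
    else:
        path.write_text(yaml.safe_dump(cfg))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=_jsonify))
    return path


def read_json_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
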