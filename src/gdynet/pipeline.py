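"""End-to-end pipeline: data generation, localization, training, evaluation.

This module wires the stages together behind plain functions so the CLI,
the test-bed and scripted experiments all run the identical code path:

    gen-data -> localize (backbone + fused layer CAMs -> RoI crops)
             -> train (inception YNet, alternating objective)
             -> infer -> evaluate (segmentation + classification reports)

``standard_config`` pins the desk-scale study conditions used throughout
the package's experiments: 200 training and 50 test images at 64 x 64, a
four-block backbone (cardinality 8, base width 16) trained for 30 epochs
with a halving schedule, CAM fusion over all four layers, and a depth-4
YNet (base 4 filters) trained for 30 epochs with batch 16, SGD momentum
0.9 and the step learning-rate schedule.  All per-stage seeds derive from
one master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import BackboneConfig, build_backbone
from .checkpoint import load_model, save_model
from .io import (DatasetManifest, read_manifest, save_prob_map,
                 write_json_report, write_manifest)
from .localize import RoIConfig, localize_dataset, train_backbone
from .metrics import evaluate_dataset
from .model import GDYNetConfig, build_gdynet
from .synthetic import SynthParams, build_dataset
from .training import TrainConfig, load_split_arrays, predict_batches, train

__all__ = ["PipelineConfig", "standard_config", "derive_seeds",
           "run_gen_data", "run_localize", "run_train", "run_infer",
           "run_evaluate", "run_ablation", "config_to_dict",
           "config_from_dict"]


@dataclass(frozen=True)
class BackboneTrainConfig:
    epochs: int = 30
    batch_size: int = 16
    lr0: float = 0.05
    lr_decay_factor: float = 2.0
    lr_decay_period: int = 10
    momentum: float = 0.9


@dataclass
class PipelineConfig:
    synth: SynthParams = field(default_factory=SynthParams)
    n_train: tuple[int, int] = (100, 100)    # (normal, glaucoma)
    n_test: tuple[int, int] = (25, 25)
    backbone: BackboneConfig = field(default_factory=lambda: BackboneConfig(
        n_blocks=4, cardinality=8, base_width=16, input_size=64))
    backbone_train: BackboneTrainConfig = field(
        default_factory=BackboneTrainConfig)
    roi: RoIConfig = field(default_factory=RoIConfig)
    model: GDYNetConfig = field(default_factory=lambda: GDYNetConfig(
        depth=4, base_filters=4, input_size=64, branch_channels=8))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=30, batch_size=16, lr0=0.1, momentum=0.9, l2=0.001,
        lr_decay_factor=2.0, lr_decay_period=20, sigma=0.5))
    seed: int = 0


def standard_config(seed: int = 0) -> PipelineConfig:
    """The package's standard desk-scale study conditions."""
    return PipelineConfig(seed=seed)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> PipelineConfig:
    """Rebuild a PipelineConfig from a (possibly partial) nested dict."""
    from .model import InceptionSpec
    from .synthetic import params_from_dict

    base = PipelineConfig()
    kwargs: dict = {"seed": int(d.get("seed", base.seed))}
    if "synth" in d:
        kwargs["synth"] = params_from_dict(d["synth"])
    for key in ("n_train", "n_test"):
        if key in d:
            kwargs[key] = tuple(int(v) for v in d[key])
    if "backbone" in d:
        kwargs["backbone"] = BackboneConfig(**d["backbone"])
    if "backbone_train" in d:
        kwargs["backbone_train"] = BackboneTrainConfig(**d["backbone_train"])
    if "roi" in d:
        kwargs["roi"] = RoIConfig(**d["roi"])
    if "model" in d:
        md = dict(d["model"])
        if "inception" in md:
            md["inception"] = InceptionSpec(**md["inception"])
        kwargs["model"] = GDYNetConfig(**md)
    if "train" in d:
        kwargs["train"] = TrainConfig(**d["train"])
    return PipelineConfig(**kwargs)


def derive_seeds(master: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2^31 from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s % (2 ** 31)) for s in ss.generate_state(n)]


def run_gen_data(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate train and test splits; returns the manifest path."""
    out = Path(out_dir)
    seeds = derive_seeds(cfg.seed)
    train_m = build_dataset(*cfg.n_train, cfg.synth, seeds[0],
                            out / "images", split="train")
    test_m = build_dataset(*cfg.n_test, cfg.synth, seeds[1],
                           out / "images", split="test")
    manifest = DatasetManifest(train_m.rows + test_m.rows)
    return write_manifest(manifest, out / "manifest.csv")


def run_localize(cfg: PipelineConfig, manifest_path: str | Path,
                 out_dir: str | Path, n_layers: int | None = None,
                 backbone_ckpt: str | Path | None = None
                 ) -> tuple[Path, dict]:
    """Stage 1: train (or load) the backbone, extract RoI crops.

    Returns the crop-manifest path and a summary dict (backbone losses,
    per-row RoI records, failure count, mean coverage).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    seeds = derive_seeds(cfg.seed)
    if backbone_ckpt is not None:
        backbone = load_model(backbone_ckpt)
        losses: list[float] = []
    else:
        backbone = build_backbone(
            dataclasses.replace(cfg.backbone, seed=seeds[2]))
        images, _, labels = load_split_arrays(manifest, "train")
        bt = cfg.backbone_train
        losses = []
        for stage in range(bt.epochs // bt.lr_decay_period + 1):
            n_ep = min(bt.lr_decay_period,
                       bt.epochs - stage * bt.lr_decay_period)
            if n_ep <= 0:
                break
            losses += train_backbone(
                backbone, images, labels, epochs=n_ep,
                batch_size=bt.batch_size,
                lr=bt.lr0 / bt.lr_decay_factor ** stage,
                momentum=bt.momentum, seed=seeds[3] + stage)
        save_model(backbone, out / "backbone.npz")
    roi = cfg.roi if n_layers is None else dataclasses.replace(
        cfg.roi, n_layers=n_layers)
    crop_manifest, records = localize_dataset(backbone, manifest,
                                              out / "crops", roi)
    crop_path = write_manifest(crop_manifest, out / "manifest_roi.csv")
    coverages = [r["coverage"] for r in records if "coverage" in r]
    summary = {
        "backbone_losses": losses,
        "n_layers": roi.n_layers,
        "records": records,
        "n_failed": sum(r["failed"] for r in records),
        "mean_coverage": (float(np.mean(coverages)) if coverages else None),
        "frac_coverage_ge_95": (float(np.mean(
            [c >= 0.95 for c in coverages])) if coverages else None),
    }
    write_json_report(summary, out / "localize_summary.json")
    return crop_path, summary


def run_train(cfg: PipelineConfig, manifest_path: str | Path,
              out_dir: str | Path):
    """Stage 2: train the joint model on the (cropped) manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    seeds = derive_seeds(cfg.seed)
    model = build_gdynet(dataclasses.replace(cfg.model, seed=seeds[4]))
    tcfg = dataclasses.replace(cfg.train, seed=seeds[5])
    model, history = train(model, manifest, tcfg, val_split="test",
                           checkpoint_dir=out)
    save_model(model, out / "model.npz")
    write_json_report({"epochs": history.to_records()},
                      out / "history.json")
    return model, history


def run_infer(model, manifest_path: str | Path, out_dir: str | Path,
              batch_size: int = 16) -> Path:
    """Write per-image probability maps and a CSV of class scores."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    rows = manifest.rows
    images = np.stack([
        _load_chw(r.image_path) for r in rows])
    probs, scores = predict_batches(model, images, batch_size)
    records = []
    for r, prob, score in zip(rows, probs, scores):
        stem = Path(r.image_path).stem
        prob_path = out / f"{stem}_prob.png"
        save_prob_map(prob, prob_path)
        records.append({"image_path": r.image_path,
                        "prob_path": str(prob_path),
                        "class_score": float(score),
                        "label": r.label, "split": r.split})
    csv_path = out / "predictions.csv"
    pd.DataFrame.from_records(records).to_csv(csv_path, index=False)
    return csv_path


def _load_chw(path) -> np.ndarray:
    from .io import load_image
    return load_image(path).transpose(2, 0, 1)


def run_evaluate(predictions_csv: str | Path, manifest_path: str | Path,
                 out_path: str | Path, split: str = "test") -> dict:
    """Aggregate predictions against the manifest's ground truth."""
    import pandas as pd

    from .errors import ValidationError
    from .io import load_mask, load_prob_map

    manifest = read_manifest(manifest_path)
    preds = pd.read_csv(predictions_csv).set_index("image_path")
    rows = manifest.subset(split).rows
    missing = [r.image_path for r in rows if r.image_path not in preds.index]
    if missing:
        raise ValidationError(
            f"missing predictions for rows: {missing[:5]}"
            + (" ..." if len(missing) > 5 else ""))
    seg_pairs, scores, labels = [], [], []
    for r in rows:
        rec = preds.loc[r.image_path]
        prob = load_prob_map(rec["prob_path"])
        if r.disc_mask_path:
            gt = load_mask(r.disc_mask_path)
            seg_pairs.append(((prob >= 0.5).astype(np.uint8), gt, prob))
        if r.label is not None:
            scores.append(float(rec["class_score"]))
            labels.append(int(r.label))
    report = evaluate_dataset(seg_pairs, np.array(scores), np.array(labels))
    report["split"] = split
    write_json_report(report, out_path)
    return report


def run_ablation(cfg: PipelineConfig, manifest_path: str | Path,
                 out_dir: str | Path, variants: tuple[int, ...] = (3, 4)
                 ) -> dict:
    """Run localize -> train -> infer -> evaluate per CAM-layer variant.

    Every variant shares the same master seed, so the only difference is
    how many per-layer CAMs enter the fusion.  Reports the side-by-side
    classification metrics and mean RoI coverage per variant.
    """
    out = Path(out_dir)
    comparison = {}
    for n_layers in variants:
        vdir = out / f"layers_{n_layers}"
        crop_path, loc_summary = run_localize(cfg, manifest_path, vdir,
                                              n_layers=n_layers)
        model, history = run_train(cfg, crop_path, vdir / "train")
        pred_csv = run_infer(model, crop_path, vdir / "infer",
                             cfg.train.batch_size)
        report = run_evaluate(pred_csv, crop_path,
                              vdir / "evaluation.json")
        comparison[str(n_layers)] = {
            "n_cam_layers": n_layers,
            "mean_roi_coverage": loc_summary["mean_coverage"],
            "frac_coverage_ge_95": loc_summary["frac_coverage_ge_95"],
            "classification": report.get("classification"),
            "segmentation": {k: report["segmentation"][k]
                             for k in ("dice", "jaccard", "accuracy",
                                       "s_measure", "e_measure")},
            "seed": cfg.seed,
        }
    result = {"variants": comparison,
              "shared_seed": cfg.seed}
    write_json_report(result, out / "ablation.json")
    return result
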