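"""Stage-1 pipeline helpers: backbone training and dataset localization.

The backbone is trained briefly as a plain image classifier (normal vs.
glaucomatous appearance) with softmax cross-entropy; its per-layer
activation gradients then drive the layer-wise CAM fusion that localizes
the optic disc in each image.  ``localize_dataset`` turns a manifest of
full-frame images into a manifest of RoI crops (with correspondingly
cropped ground-truth masks) ready for the segmentation network, logging
each RoI box and any localization failures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .backbone import ResNeXtBackbone, collect
from .cam import box_coverage, crop_mask, extract_roi, fuse_cams, layer_cam
from .errors import LocalizationError
from .io import (DatasetManifest, ManifestRow, load_image, load_mask,
                 save_image, save_mask)
from .nn import SGDM, Tensor

__all__ = ["RoIConfig", "train_backbone", "localize_dataset",
           "softmax_cross_entropy"]


@dataclass(frozen=True)
class RoIConfig:
    n_layers: int = 4            # how many (deepest-first count) CAM layers
    threshold_frac: float = 0.2
    margin_frac: float = 0.25
    out_size: int = 64
    fusion: str = "max"
    class_selector: int | str = "argmax"


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax logits."""
    z = logits - Tensor(logits.data.max(axis=1, keepdims=True))  # stability
    logsumexp = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - logsumexp
    n = logits.shape[0]
    onehot = np.zeros(logits.shape)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def train_backbone(backbone: ResNeXtBackbone, images: np.ndarray,
                   labels: np.ndarray, *, epochs: int = 5,
                   batch_size: int = 16, lr: float = 0.01,
                   momentum: float = 0.9, l2: float = 0.0,
                   seed: int = 0) -> list[float]:
    """Brief supervised training of the CAM backbone; returns epoch losses.

    ``images`` is (N, 3, H, W) in [0, 1]; ``labels`` integer classes.
    """
    rng = np.random.default_rng(seed)
    opt = SGDM(backbone, lr=lr, momentum=momentum, l2=l2)
    losses = []
    n = len(images)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = backbone(Tensor(images[idx]))
            loss = softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss.append(float(loss.data))
        losses.append(float(np.mean(epoch_loss)))
    return losses


def fused_cam_for_image(backbone: ResNeXtBackbone, image: np.ndarray,
                        roi: RoIConfig):
    """Collect activation gradients and fuse the selected layers' CAMs."""
    stack = collect(backbone, image, roi.class_selector)
    layers = list(range(stack.n_layers))[:roi.n_layers]
    cams = [layer_cam(stack, layer) for layer in layers]
    return fuse_cams(cams, target_size=image.shape[0], method=roi.fusion)


def localize_dataset(backbone: ResNeXtBackbone, manifest: DatasetManifest,
                     out_dir: str | Path, roi: RoIConfig = RoIConfig()
                     ) -> tuple[DatasetManifest, list[dict]]:
    """Localize every manifest row; write crops and return the new manifest.

    Returns ``(crop_manifest, records)`` where each record logs the image
    path, RoI box, disc-pixel coverage (when a ground-truth mask exists),
    and whether localization fell back to a centered crop after failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, records = [], []
    for i, row in enumerate(manifest.rows):
        image = load_image(row.image_path)
        record: dict = {"index": i, "image_path": row.image_path,
                        "failed": False}
        try:
            cam = fused_cam_for_image(backbone, image, roi)
            region = extract_roi(cam, image,
                                 threshold_frac=roi.threshold_frac,
                                 margin_frac=roi.margin_frac,
                                 out_size=roi.out_size)
            box = region.box
            crop = region.crop
        except LocalizationError as exc:
            # fall back to a centered crop covering the central window
            record["failed"] = True
            record["error"] = str(exc)
            h, w = image.shape[:2]
            q_h, q_w = h // 4, w // 4
            box = (q_h, h - q_h, q_w, w - q_w)
            from skimage.transform import resize
            crop = resize(image[box[0]:box[1], box[2]:box[3]],
                          (roi.out_size, roi.out_size, image.shape[2]),
                          order=1, mode="edge", anti_aliasing=False,
                          preserve_range=True)
        record["box"] = list(map(int, box))
        stem = Path(row.image_path).stem
        crop_path = out / f"{stem}_roi.png"
        save_image(crop, crop_path)
        mask_path = None
        if row.disc_mask_path:
            gt = load_mask(row.disc_mask_path)
            record["coverage"] = box_coverage(box, gt)
            cropped = crop_mask(gt, box, roi.out_size)
            mask_path = out / f"{stem}_roi_disc.png"
            save_mask(cropped, mask_path)
        rows.append(ManifestRow(image_path=str(crop_path),
                                disc_mask_path=(str(mask_path)
                                                if mask_path else None),
                                label=row.label, split=row.split,
                                cdr=row.cdr))
        records.append(record)
    return DatasetManifest(rows), records
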