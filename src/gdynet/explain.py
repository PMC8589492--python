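"""Explainability: Grad-CAM of the classification branch.

The branch's convolutional stage is the last spatial layer before the
class score, so its Grad-CAM shows which part of the (masked) disc drives
the glaucoma decision.  Channel weights are the spatial means of the
class-score gradients; the map is the rectified weighted channel sum,
min-max normalized and upsampled to the input frame.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .model import GDYNet

__all__ = ["explain_image", "overlay_heatmap"]


def explain_image(model: GDYNet, image: np.ndarray
                  ) -> tuple[np.ndarray, float]:
    """Grad-CAM heatmap (input-sized, in [0, 1]) and the class score."""
    model.zero_grad()
    out = model(image)
    out.class_score.backward(np.ones(out.class_score.shape))
    act = out.branch_conv.data[0]
    grad = (out.branch_conv.grad[0] if out.branch_conv.grad is not None
            else np.zeros_like(act))
    weights = grad.mean(axis=(1, 2), keepdims=True)
    cam = np.maximum((weights * act).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    size = model.cfg.input_size
    heat = resize(cam, (size, size), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    return np.clip(heat, 0.0, 1.0), float(out.class_score.data.reshape(-1)[0])


def overlay_heatmap(image: np.ndarray, heat: np.ndarray,
                    alpha: float = 0.45) -> np.ndarray:
    """Blend a red-yellow heatmap over an RGB image (both in [0, 1])."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    color = np.stack([heat, heat ** 2, np.zeros_like(heat)], axis=-1)
    return np.clip((1 - alpha) * img + alpha * color, 0.0, 1.0)
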