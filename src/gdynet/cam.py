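"""Class activation maps and region-of-interest extraction.

Layer-wise CAM construction: at every spatial location the class-score
gradient is rectified to give a per-location, per-channel weight,

    W_ij^f = relu(g_ij^f),

the weights multiply the activations pointwise,

    F'_ij^f = W_ij^f * F_ij^f,

and the map is the rectified channel sum,

    C = relu(sum_f F'_ij^f).

Grad-CAM instead weights each channel by the spatial mean of its
gradients.  Per-layer maps are min-max normalized, bilinearly upsampled
to a common size and fused (element-wise maximum by default, which
preserves the fine detail contributed by shallow layers; mean fusion is
available for ablation).  The fused map is thresholded, the largest
8-connected component kept, and its padded, squared bounding box becomes
the crop fed to the segmentation network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .backbone import FeatureMapStack
from .errors import DomainError, LocalizationError, ShapeError

__all__ = ["ClassActivationMap", "RoIRegion", "layer_cam", "grad_cam",
           "fuse_cams", "extract_roi", "box_coverage", "crop_mask"]


@dataclass
class ClassActivationMap:
    values: np.ndarray          # (H, W), nonnegative
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("CAM must be 2-d")
        if (self.values < 0).any():
            raise DomainError("CAM values must be nonnegative")
        if self.normalized and self.values.max() > 1.0 + 1e-9:
            raise DomainError("normalized CAM must not exceed 1")


@dataclass
class RoIRegion:
    box: tuple[int, int, int, int]   # half-open (row0, row1, col0, col1)
    mask: np.ndarray                 # thresholded-CAM support, full frame
    crop: np.ndarray                 # image patch resized to out_size


def layer_cam(stack: FeatureMapStack, layer: int) -> ClassActivationMap:
    """Per-location gradient-weighted CAM of one backbone layer."""
    acts = stack.activations[layer]
    grads = stack.gradients[layer]
    weights = np.maximum(grads, 0.0)
    weighted = weights * acts
    cam = np.maximum(weighted.sum(axis=0), 0.0)
    return ClassActivationMap(values=cam, normalized=False)


def grad_cam(stack: FeatureMapStack, layer: int) -> ClassActivationMap:
    """Channel-weighted CAM: weights are spatial means of the gradients."""
    acts = stack.activations[layer]
    grads = stack.gradients[layer]
    weights = grads.mean(axis=(1, 2), keepdims=True)
    cam = np.maximum((weights * acts).sum(axis=0), 0.0)
    return ClassActivationMap(values=cam, normalized=False)


def _normalize(values: np.ndarray) -> np.ndarray:
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        # identically-zero maps stay zero; flat positive maps saturate
        return (np.ones_like(values) if vmax > 0.0
                else np.zeros_like(values))
    return (values - vmin) / (vmax - vmin)


def fuse_cams(cams: list[ClassActivationMap], target_size: int,
              method: str = "max") -> ClassActivationMap:
    """Fuse per-layer CAMs into one map at ``target_size``.

    Each CAM is min-max normalized, bilinearly upsampled, then combined
    element-wise (``max`` default, ``mean`` for the ablation harness; the
    mean is re-normalized so the output contract is uniform).
    """
    if not cams:
        raise ValueError("fuse_cams requires at least one CAM")
    resized = []
    for cam in cams:
        v = _normalize(cam.values)
        if v.shape != (target_size, target_size):
            v = resize(v, (target_size, target_size), order=1,
                       mode="edge", anti_aliasing=False,
                       preserve_range=True)
        resized.append(np.clip(v, 0.0, 1.0))
    if method == "max":
        fused = np.maximum.reduce(resized)
    elif method == "mean":
        fused = _normalize(np.mean(resized, axis=0))
    else:
        raise DomainError(f"unknown fusion method: {method!r}")
    return ClassActivationMap(values=fused, normalized=True)


def extract_roi(cam: ClassActivationMap, image: np.ndarray,
                threshold_frac: float = 0.2, margin_frac: float = 0.25,
                out_size: int = 64) -> RoIRegion:
    """Threshold the fused CAM and crop the dominant component.

    The binary support at ``threshold_frac`` is reduced to its largest
    8-connected component; the component's bounding box is expanded by
    ``margin_frac`` of its side per side, squared to the longer side, and
    clipped to the image; the crop is resized to ``out_size``.
    """
    if not cam.normalized:
        raise DomainError("extract_roi expects a normalized CAM")
    values = cam.values
    h, w = values.shape
    support = values >= threshold_frac
    if not support.any():
        raise LocalizationError(
            "CAM support is empty at the given threshold")
    labels, n = ndimage.label(support, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(support, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        component = labels == keep
    else:
        component = support
    rows, cols = np.where(component)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    mr = margin_frac * (r1 - r0)
    mc = margin_frac * (c1 - c0)
    r0f, r1f = r0 - mr, r1 + mr
    c0f, c1f = c0 - mc, c1 + mc
    side = max(r1f - r0f, c1f - c0f)
    rc, cc = (r0f + r1f) / 2.0, (c0f + c1f) / 2.0
    r0, r1 = _fit_interval(rc, side, h)
    c0, c1 = _fit_interval(cc, side, w)
    img = np.asarray(image, dtype=np.float64)
    crop = img[r0:r1, c0:c1]
    crop = resize(crop, (out_size, out_size) + crop.shape[2:], order=1,
                  mode="edge", anti_aliasing=False, preserve_range=True)
    return RoIRegion(box=(r0, r1, c0, c1), mask=component.astype(np.uint8),
                     crop=crop)


def _fit_interval(center: float, side: float, limit: int) -> tuple[int, int]:
    """Integer interval of length ~side around center, shifted into
    [0, limit] before clipping, so squares survive near borders."""
    lo = center - side / 2.0
    hi = center + side / 2.0
    if lo < 0:
        hi -= lo
        lo = 0.0
    if hi > limit:
        lo -= hi - limit
        hi = float(limit)
    lo = max(int(np.floor(lo)), 0)
    hi = min(int(np.ceil(hi)), limit)
    return lo, max(hi, lo + 1)


def box_coverage(box: tuple[int, int, int, int], gt_mask: np.ndarray
                 ) -> float:
    """Fraction of ground-truth foreground pixels inside the box."""
    gt = np.asarray(gt_mask) > 0
    total = gt.sum()
    if total == 0:
        raise DomainError("ground-truth mask is empty")
    r0, r1, c0, c1 = box
    return float(gt[r0:r1, c0:c1].sum() / total)


def crop_mask(mask: np.ndarray, box: tuple[int, int, int, int],
              out_size: int) -> np.ndarray:
    """Crop and nearest-resize a binary mask to the RoI frame."""
    r0, r1, c0, c1 = box
    sub = np.asarray(mask)[r0:r1, c0:c1].astype(np.float64)
    out = resize(sub, (out_size, out_size), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)
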