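"""Synthetic fundus-like image generation with known disc/cup geometry.

Real fundus photographs show a bright elliptical optic disc containing a
brighter concentric optic cup, dark curvilinear vessels, a smooth
background intensity gradient, and sensor noise.  Glaucoma risk is read
from the cup-to-disc ratio (CDR): the vertical cup diameter divided by the
vertical disc diameter, with larger values indicating glaucomatous
cupping.  This module emulates exactly those features so that the
localizer, the segmentation network, and the classifier are all trainable
and testable without any external dataset.

The disc is deliberately *not* centered in the frame (clinical images are
acquired at varying orientations), and the disc/cup are ellipses of
random eccentricity and rotation rather than circles.

Geometry is constructed so that the rasterized masks reproduce the drawn
CDR exactly at pixel resolution: the vertical half-chords of disc and cup
are snapped to half-integer pixel values (choosing among a few candidate
chord lengths the pair whose count ratio best matches the drawn CDR), so
the mask-measured diameter ratio agrees with the stored ``cdr`` within
2/image_size even at 64 x 64.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = ["SynthParams", "SyntheticSample", "render_sample", "assign_label",
           "build_dataset"]


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    Intensities are grayscale levels in [0, 1] on the dominant (red)
    channel; fractions are relative to ``image_size``.
    """

    image_size: int = 64
    disc_radius_range: tuple[float, float] = (0.10, 0.20)
    disc_center_jitter: float = 0.15
    cdr_normal_range: tuple[float, float] = (0.25, 0.45)
    cdr_glaucoma_range: tuple[float, float] = (0.60, 0.85)
    cdr_threshold: float = 0.525
    disc_intensity: float = 0.75
    cup_intensity: float = 0.95
    background_base: float = 0.35
    background_gradient: float = 0.08
    max_axis_ratio: float = 1.25
    vessel_count: int = 4
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ConfigurationError("image_size must be >= 16")
        lo, hi = self.disc_radius_range
        if not 0 < lo <= hi < 0.5:
            raise ConfigurationError("disc_radius_range must satisfy "
                                     "0 < lo <= hi < 0.5")
        n_lo, n_hi = self.cdr_normal_range
        g_lo, g_hi = self.cdr_glaucoma_range
        if not (0 < n_lo <= n_hi and g_lo <= g_hi < 1):
            raise ConfigurationError("cdr ranges must lie in (0, 1)")
        if n_hi >= g_lo:
            raise ConfigurationError(
                "cdr ranges must be disjoint: max normal < min glaucoma")
        if not (n_hi < self.cdr_threshold < g_lo):
            raise ConfigurationError("cdr_threshold must separate the ranges")
        levels = (self.background_base, self.disc_intensity,
                  self.cup_intensity)
        if not all(0.0 <= v <= 1.0 for v in levels):
            raise ConfigurationError("intensity levels must lie in [0, 1]")
        if not (self.cup_intensity > self.disc_intensity
                > self.background_base):
            raise ConfigurationError(
                "required ordering: cup > disc > background intensity")
        if self.max_axis_ratio < 1.0:
            raise ConfigurationError("max_axis_ratio must be >= 1")
        if self.vessel_count < 0 or self.noise_sd < 0:
            raise ConfigurationError("vessel_count and noise_sd must be >= 0")


@dataclass
class SyntheticSample:
    """One generated image with its ground truth."""

    image: np.ndarray          # (H, W, 3) float in [0, 1]
    disc_mask: np.ndarray      # (H, W) uint8 {0, 1}
    cup_mask: np.ndarray       # (H, W) uint8 {0, 1}
    cdr: float                 # vertical cup/disc diameter ratio in (0, 1)
    label: int                 # 0 = normal, 1 = glaucoma
    meta: dict = field(default_factory=dict)


def assign_label(cdr: float, threshold: float) -> int:
    """Classify by cup-to-disc ratio: 1 (glaucoma) iff ``cdr > threshold``.

    The tie ``cdr == threshold`` maps to 0 (strict inequality): a borderline
    ratio is not called glaucomatous.
    """
    if not 0.0 < cdr < 1.0:
        raise DomainError(f"cdr must lie in (0, 1), got {cdr}")
    return int(cdr > threshold)


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    """Filled rotated ellipse: pixel centers with quadratic form <= 1.

    ``a`` is the semi-axis along the (pre-rotation) column direction,
    ``b`` along the row direction; ``theta`` rotates the axes.
    """
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = rr - cy, cc - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _vertical_half_chord(a: float, b: float, theta: float) -> float:
    """Half-length of the vertical chord through a rotated ellipse center."""
    return 1.0 / np.sqrt(np.sin(theta) ** 2 / a ** 2
                         + np.cos(theta) ** 2 / b ** 2)


def _pick_chords(h0: float, cdr: float, h_lo: float, h_hi: float
                 ) -> tuple[int, int]:
    """Choose integer vertical chord counts (D, C) with C/D closest to cdr.

    Scans disc chord counts D near ``2 * h0`` (kept within the configured
    radius range, widened by one pixel for quantization) and pairs each
    with the rounded cup count.
    """
    d0 = int(round(2.0 * h0))
    best: tuple[float, int, int] | None = None
    for d in range(d0 - 2, d0 + 3):
        if d < 4 or d / 2.0 < h_lo - 1.0 or d / 2.0 > h_hi + 1.0:
            continue
        c = int(round(cdr * d))
        c = max(2, min(c, d - 2))
        err = abs(c / d - cdr)
        if best is None or err < best[0]:
            best = (err, d, c)
    assert best is not None
    return best[1], best[2]


def render_sample(params: SynthParams, label: int, seed: int
                  ) -> SyntheticSample:
    """Render one deterministic sample for the given class label.

    The CDR is drawn uniformly from the label's configured range; masks are
    filled (rotated) ellipses; vessels are dark random-walk polylines;
    Gaussian noise is added last and the image clipped to [0, 1].
    """
    if label not in (0, 1):
        raise DomainError(f"label must be 0 or 1, got {label}")
    p = params
    s = p.image_size
    rng = np.random.default_rng(seed)

    cdr_lo, cdr_hi = (p.cdr_glaucoma_range if label == 1
                      else p.cdr_normal_range)
    cdr = float(rng.uniform(cdr_lo, cdr_hi))

    h_lo, h_hi = p.disc_radius_range[0] * s, p.disc_radius_range[1] * s
    h0 = rng.uniform(h_lo, h_hi)          # nominal vertical half-chord
    theta = rng.uniform(0.0, np.pi)
    ratio = rng.uniform(1.0, p.max_axis_ratio)  # column/row semi-axis ratio

    d_count, c_count = _pick_chords(h0, cdr, h_lo, h_hi)
    h_disc, h_cup = d_count / 2.0, c_count / 2.0
    # semi-axes (a along columns, b along rows) realizing the exact
    # vertical half-chord h_disc at rotation theta, with a = ratio * b
    b_disc = h_disc * np.sqrt(np.cos(theta) ** 2
                              + np.sin(theta) ** 2 / ratio ** 2)
    a_disc = ratio * b_disc
    scale = h_cup / h_disc
    a_cup, b_cup = a_disc * scale, b_disc * scale

    # integer center, constrained so the disc fits with a 2-pixel margin
    # and stays inside the central window (off-center, never off-image)
    max_r = max(a_disc, b_disc)
    jit = p.disc_center_jitter * s
    lo = max(max_r + 2.0, s / 2.0 - jit)
    hi = min(s - 1 - max_r - 2.0, s / 2.0 + jit)
    if lo > hi:
        lo = hi = s / 2.0
    cy = int(round(rng.uniform(lo, hi)))
    cx = int(round(rng.uniform(lo, hi)))

    # parity: odd chord counts center on a pixel row, even counts on a
    # half-integer row, so the rasterized count equals the target exactly
    oy_d = 0.0 if d_count % 2 == 1 else 0.5
    oy_c = 0.0 if c_count % 2 == 1 else 0.5
    disc_mask = _ellipse_mask(s, cy + oy_d, cx, a_disc, b_disc, theta)
    cup_mask = _ellipse_mask(s, cy + oy_c, cx, a_cup, b_cup, theta)
    cup_mask &= disc_mask  # guard: cup strictly inside disc by construction

    # background with a smooth directional gradient
    gdir = rng.uniform(0.0, 2.0 * np.pi)
    rr, cc = np.mgrid[0:s, 0:s] / max(s - 1, 1)
    ramp = (rr - 0.5) * np.sin(gdir) + (cc - 0.5) * np.cos(gdir)
    gray = p.background_base + p.background_gradient * ramp
    gray = np.clip(gray, 0.0, 1.0)
    gray[disc_mask == 1] = p.disc_intensity
    gray[cup_mask == 1] = p.cup_intensity

    vessel = _draw_vessels(s, p.vessel_count, rng)
    gray = np.where(vessel, gray * 0.45, gray)

    # RGB: red carries the full disc contrast, green/blue attenuated
    image = np.stack([gray, 0.55 * gray, 0.30 * gray], axis=-1)
    if p.noise_sd > 0:
        image = image + rng.normal(0.0, p.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    measured = float(c_count) / float(d_count)
    return SyntheticSample(image=image, disc_mask=disc_mask,
                           cup_mask=cup_mask, cdr=measured, label=label,
                           meta={"center": (cy, cx), "theta": float(theta),
                                 "semi_axes": (float(a_disc), float(b_disc)),
                                 "drawn_cdr": cdr, "seed": int(seed)})


def _draw_vessels(size: int, count: int, rng: np.random.Generator
                  ) -> np.ndarray:
    """Dark curvilinear vessels as momentum random walks from the border."""
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(count):
        edge = rng.integers(0, 4)
        t = rng.uniform(0.1, 0.9) * size
        pos = {0: [0.0, t], 1: [size - 1.0, t],
               2: [t, 0.0], 3: [t, size - 1.0]}[int(edge)]
        pos = np.array(pos)
        target = np.array([size / 2.0, size / 2.0]) + rng.uniform(
            -0.25 * size, 0.25 * size, size=2)
        heading = target - pos
        heading /= np.linalg.norm(heading) + 1e-12
        for _ in range(2 * size):
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < size and 0 <= c < size):
                break
            mask[max(r - 1, 0):r + 1, max(c - 1, 0):c + 1] = True
            heading = heading + rng.normal(0.0, 0.25, size=2)
            heading /= np.linalg.norm(heading) + 1e-12
            pos = pos + 1.5 * heading
    return mask


def build_dataset(n_normal: int, n_glaucoma: int, params: SynthParams,
                  seed: int, out_dir: str | Path, split: str = "train"):
    """Render and write a labelled dataset; returns its manifest.

    Per-sample seeds derive deterministically from ``(seed, index)`` via a
    seed sequence, so the dataset is reproducible and each sample is
    independent of the total count.
    """
    from .io import DatasetManifest, ManifestRow, save_image, save_mask

    if n_normal < 0 or n_glaucoma < 0:
        raise DomainError("sample counts must be >= 0")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    labels = [0] * n_normal + [1] * n_glaucoma
    for i, label in enumerate(labels):
        sub_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0]
                       % (2 ** 31))
        sample = render_sample(params, label, sub_seed)
        img_path = out / f"{split}_{i:04d}.png"
        mask_path = out / f"{split}_{i:04d}_disc.png"
        cup_path = out / f"{split}_{i:04d}_cup.png"
        save_image(sample.image, img_path)
        save_mask(sample.disc_mask, mask_path)
        save_mask(sample.cup_mask, cup_path)
        rows.append(ManifestRow(image_path=str(img_path),
                                disc_mask_path=str(mask_path),
                                label=label, split=split,
                                cdr=sample.cdr))
    return DatasetManifest(rows=rows)


def params_to_dict(params: SynthParams) -> dict:
    return dataclasses.asdict(params)


def params_from_dict(d: dict) -> SynthParams:
    d = dict(d)
    for key in ("disc_radius_range", "cdr_normal_range",
                "cdr_glaucoma_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SynthParams(**d)
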