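"""The joint segmentation-classification network (inception-block YNet).

A U-shaped encoder-decoder segments the optic disc; a light classification
branch grafted onto it scores glaucoma.  Every convolutional stage is an
inception block running four parallel branches - 1x1 convolution,
1x1 -> 3x3, 1x1 -> two cascaded 3x3 (the factorized 5x5 receptive field),
and 3x3 max-pool -> 1x1 - whose outputs are channel-concatenated, so each
stage sees the disc at several receptive-field scales at once (disc size
and orientation vary strongly between images).

Encoder: ``depth`` levels of inception block + 2x2 max-pool, filter count
doubling per level; a bottleneck inception block at the lowest resolution;
decoder mirroring with 2x bilinear upsampling and skip concatenation; a
1x1 convolution head with pixel-wise sigmoid yields the disc probability
map.

Classification branch: the predicted disc mask (probability map binarized
at 0.5, a hard non-differentiable mask; or the soft map itself when
``soft_mask`` is set, keeping the branch differentiable through the
decoder) multiplies the input image, the product is 2x average-pooled,
the bottleneck feature map is bilinearly upsampled to the same size and
concatenated, and a stride-2 3x3 convolution halves the spatial size.
The activations are then average-pooled *over the predicted disc
support* (not the whole frame: disc size varies several-fold between
eyes, and the glaucoma cue - the cup-to-disc ratio - is a statistic
relative to the disc, which frame-global pooling washes out) and fed to
two fully connected sigmoid layers (hidden width ``classifier_hidden``)
that emit the scalar glaucoma score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import Conv2d, Linear, Module, Tensor, concat
from .nn.layers import BatchNorm1d, GroupNorm

__all__ = ["InceptionSpec", "GDYNetConfig", "InceptionBlock", "GDYNet",
           "ModelOutputs", "build_gdynet"]


@dataclass(frozen=True)
class InceptionSpec:
    """Out-channels of the four parallel branches of an inception block."""

    c1: int = 2        # 1x1 convolution
    c3: int = 4        # 1x1 reduce -> 3x3
    c5: int = 1        # 1x1 reduce -> cascaded 3x3 (5x5 receptive field)
    cpool: int = 1     # 3x3 max-pool -> 1x1

    def __post_init__(self):
        if min(self.c1, self.c3, self.c5, self.cpool) < 1:
            raise ConfigurationError("all branch channel counts must be >= 1")

    @property
    def total(self) -> int:
        return self.c1 + self.c3 + self.c5 + self.cpool

    def scaled(self, total: int) -> "InceptionSpec":
        """Distribute ``total`` channels across branches proportionally."""
        raw = np.array([self.c1, self.c3, self.c5, self.cpool], float)
        out = np.maximum(np.round(raw * total / raw.sum()), 1).astype(int)
        # adjust the widest branch so the sum is exact
        out[int(np.argmax(out))] += total - out.sum()
        if out.min() < 1:
            raise ConfigurationError(f"cannot split {total} channels 4 ways")
        return InceptionSpec(*map(int, out))


@dataclass(frozen=True)
class GDYNetConfig:
    depth: int = 4
    base_filters: int = 8
    input_size: int = 64
    inception: InceptionSpec = field(default_factory=InceptionSpec)
    classifier_hidden: int = 64
    branch_channels: int = 2   # channels of the classification-branch conv
    soft_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.input_size % (2 ** self.depth):
            raise ConfigurationError(
                f"input_size={self.input_size} must be divisible by "
                f"2^depth={2 ** self.depth}")
        if self.classifier_hidden < 1:
            raise ConfigurationError("classifier_hidden must be >= 1")
        if self.base_filters < 4:
            raise ConfigurationError("base_filters must be >= 4")


class InceptionBlock(Module):
    """Four parallel branches, channel-concatenated; spatial size kept."""

    def __init__(self, c_in: int, spec: InceptionSpec, *,
                 rng: np.random.Generator):
        if c_in < 1:
            raise ConfigurationError("input channels must be >= 1")
        self.spec = spec
        r3 = max(spec.c3 // 2, 1)
        r5 = max(spec.c5 // 2, 1)
        self.b1 = Conv2d(c_in, spec.c1, 1, rng=rng)
        self.b3_reduce = Conv2d(c_in, r3, 1, rng=rng)
        self.b3 = Conv2d(r3, spec.c3, 3, padding=1, rng=rng)
        self.b5_reduce = Conv2d(c_in, r5, 1, rng=rng)
        self.b5a = Conv2d(r5, r5, 3, padding=1, rng=rng)
        self.b5b = Conv2d(r5, spec.c5, 3, padding=1, rng=rng)
        self.bpool = Conv2d(c_in, spec.cpool, 1, rng=rng)
        self.norm = GroupNorm(spec.total)

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.b1(x).leaky_relu()
        y3 = self.b3(self.b3_reduce(x).leaky_relu()).leaky_relu()
        y5 = self.b5b(
            self.b5a(self.b5_reduce(x).leaky_relu()).leaky_relu()
        ).leaky_relu()
        yp = self.bpool(x.max_pool2d_same(3)).leaky_relu()
        return self.norm(concat([y1, y3, y5, yp], axis=1))


@dataclass
class ModelOutputs:
    """One forward pass: per-pixel disc probability + scalar class score."""

    seg_prob: Tensor      # (N, H, W) in [0, 1]
    class_score: Tensor   # (N,) in [0, 1]
    bottleneck: Tensor    # low-level encoder features used by the branch
    branch_conv: Tensor   # branch conv activation (Grad-CAM target)

    def seg_prob_numpy(self) -> np.ndarray:
        return self.seg_prob.data

    def class_score_numpy(self) -> np.ndarray:
        return self.class_score.data


class GDYNet(Module):
    def __init__(self, cfg: GDYNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = [cfg.base_filters * (2 ** i) for i in range(cfg.depth + 1)]
        self.encoder: list[InceptionBlock] = []
        c_in = 3
        for i in range(cfg.depth):
            self.encoder.append(
                InceptionBlock(c_in, cfg.inception.scaled(f[i]), rng=rng))
            c_in = f[i]
        self.bottleneck = InceptionBlock(
            c_in, cfg.inception.scaled(f[cfg.depth]), rng=rng)
        self.decoder: list[InceptionBlock] = []
        c_up = f[cfg.depth]
        for i in reversed(range(cfg.depth)):
            self.decoder.append(InceptionBlock(
                c_up + f[i], cfg.inception.scaled(f[i]), rng=rng))
            c_up = f[i]
        self.head = Conv2d(c_up, 1, 1, rng=rng)
        # classification branch
        self.branch_conv = Conv2d(3 + f[cfg.depth], cfg.branch_channels, 3,
                                  stride=2, padding=1, rng=rng)
        self.feat_norm = BatchNorm1d(cfg.branch_channels)
        self.fc1 = Linear(cfg.branch_channels, cfg.classifier_hidden,
                          rng=rng)
        self.fc2 = Linear(cfg.classifier_hidden, 1, rng=rng)

    # -- forward ----------------------------------------------------------

    def forward(self, images: Tensor | np.ndarray) -> ModelOutputs:
        x = self._as_input(images)
        skips: list[Tensor] = []
        for block in self.encoder:
            y = block(x)
            skips.append(y)
            x = y.max_pool2d(2)
        bottom = self.bottleneck(x)
        x = bottom
        for block, skip in zip(self.decoder, reversed(skips)):
            x = x.upsample_bilinear(skip.shape[2:])
            if x.shape[2:] != skip.shape[2:]:
                raise ShapeError("encoder/decoder skip shapes diverge")
            x = block(concat([x, skip], axis=1))
        seg_logit = self.head(x)
        seg_prob = seg_logit.sigmoid()          # (N, 1, H, W)
        score, branch_act = self._classify(self._as_input(images), seg_prob,
                                           bottom)
        n = seg_prob.shape[0]
        return ModelOutputs(
            seg_prob=seg_prob.reshape(n, *seg_prob.shape[2:]),
            class_score=score.reshape(n),
            bottleneck=bottom, branch_conv=branch_act)

    def _classify(self, image: Tensor, seg_prob: Tensor, bottom: Tensor
                  ) -> tuple[Tensor, Tensor]:
        if self.cfg.soft_mask:
            mask = seg_prob
        else:
            # hard mask: gradients reach the encoder through the
            # bottleneck path, not through the binarization
            mask = Tensor((seg_prob.data >= 0.5).astype(np.float64))
        masked = image * mask                   # broadcast over channels
        pooled = masked.avg_pool2d(2)
        low = bottom.upsample_bilinear(pooled.shape[2:])
        fused = concat([pooled, low], axis=1)
        act = self.branch_conv(fused).leaky_relu()
        # average pooling restricted to the predicted disc support: disc
        # size varies several-fold between eyes, so statistics must be
        # relative to the disc, not the frame (the glaucoma cue is the
        # cup-to-disc ratio, which frame-global averages wash out)
        mask_lo = mask.avg_pool2d(image.shape[-1] // act.shape[-1])
        supp = mask_lo.sum(axis=(2, 3))                    # (N, 1)
        feat = (act * mask_lo).sum(axis=(2, 3)) * ((supp + 1e-6) ** -1.0)
        # standardize the pooled features: their raw scale is tiny and
        # sample-to-sample spread tinier, which stalls the sigmoid head
        feat = self.feat_norm(feat)
        hidden = self.fc1(feat).sigmoid()
        return self.fc2(hidden).sigmoid(), act

    def _as_input(self, images) -> Tensor:
        if isinstance(images, Tensor):
            x = images
        else:
            arr = np.asarray(images, dtype=np.float64)
            if arr.ndim == 3 and arr.shape[-1] == 3:     # single HWC image
                arr = arr.transpose(2, 0, 1)[None]
            elif arr.ndim == 4 and arr.shape[-1] == 3:   # batch of HWC
                arr = arr.transpose(0, 3, 1, 2)
            elif arr.ndim != 4:
                raise ShapeError(f"unsupported image array {arr.shape}")
            x = Tensor(arr)
        if x.shape[-1] != self.cfg.input_size or \
                x.shape[-2] != self.cfg.input_size:
            raise ShapeError(
                f"input spatial size {x.shape[-2:]} != configured "
                f"{self.cfg.input_size}")
        return x

    def encoder_spatial_sizes(self) -> list[int]:
        """Spatial size seen by each encoder block plus the bottleneck."""
        s = self.cfg.input_size
        sizes = []
        for _ in range(self.cfg.depth):
            sizes.append(s)
            s //= 2
        sizes.append(s)
        return sizes


def build_gdynet(cfg: GDYNetConfig) -> GDYNet:
    """Construct the joint model with deterministic initialization."""
    return GDYNet(cfg)


def calibrate_feature_norm(model: GDYNet, images, batch_size: int = 16
                           ) -> None:
    """Set the branch feature-norm running stats exactly from data.

    Runs forward passes over ``images`` (N, 3, H, W) and replaces the
    exponential running statistics with the exact mean/variance of the
    pooled branch features, closing the small-batch train/eval gap.
    """
    feats = []
    for i in range(0, len(images), batch_size):
        model(Tensor(np.asarray(images[i:i + batch_size])))
        feats.append(model.feat_norm.last_input)
    model.feat_norm.calibrate(np.concatenate(feats))
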