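"""Stage-1 classifier backbone: a small ResNeXt-style network.

Each block follows the split-transform-merge strategy: a 1x1 channel
expansion, a 3x3 *grouped* convolution whose group count is the block
cardinality (the parallel transformation paths, summed implicitly by the
following pointwise convolution), a 1x1 merge, and an identity skip
(projected by a strided 1x1 convolution when shape changes).  Blocks
downsample by stride 2, so an ``input_size`` of 64 with four blocks
yields activation maps of 32, 16, 8 and 4 pixels - the multi-resolution
stack from which the layer-wise class activation maps are built.

The backbone is trained from scratch on the synthetic classification
task (normal vs. glaucomatous appearance); checkpoint loading is
supported for parity experiments with externally trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import Conv2d, Linear, Module, Tensor
from .nn.layers import GroupNorm

__all__ = ["BackboneConfig", "ResNeXtBackbone", "FeatureMapStack",
           "build_backbone", "collect"]


@dataclass(frozen=True)
class BackboneConfig:
    n_blocks: int = 4
    cardinality: int = 32
    base_width: int = 32
    input_size: int = 64
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.cardinality < 1:
            raise ConfigurationError("cardinality must be >= 1")
        if self.base_width % self.cardinality:
            raise ConfigurationError(
                f"base_width={self.base_width} must be divisible by "
                f"cardinality={self.cardinality}")
        if self.input_size % (2 ** self.n_blocks):
            raise ConfigurationError(
                f"input_size={self.input_size} must be divisible by "
                f"2^n_blocks={2 ** self.n_blocks}")


class ResNeXtBlock(Module):
    """1x1 expand -> 3x3 grouped (stride 2) -> 1x1 merge, plus skip."""

    def __init__(self, c_in: int, c_out: int, cardinality: int,
                 rng: np.random.Generator, stride: int = 2):
        if c_out % cardinality:
            raise ConfigurationError(
                f"block width {c_out} not divisible by "
                f"cardinality {cardinality}")
        self.conv_in = Conv2d(c_in, c_out, 1, rng=rng)
        self.conv_group = Conv2d(c_out, c_out, 3, stride=stride, padding=1,
                                 groups=cardinality, rng=rng)
        self.conv_out = Conv2d(c_out, c_out, 1, rng=rng)
        self.proj = Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
        self.norm1 = GroupNorm(c_out, groups=1)
        self.norm2 = GroupNorm(c_out, groups=cardinality)
        self.norm3 = GroupNorm(c_out, groups=1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv_in(x)).leaky_relu()
        y = self.norm2(self.conv_group(y)).leaky_relu()
        y = self.norm3(self.conv_out(y))
        return (y + self.proj(x)).leaky_relu()


class ResNeXtBackbone(Module):
    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks: list[ResNeXtBlock] = []
        c_in = 3
        for i in range(cfg.n_blocks):
            c_out = cfg.base_width * (2 ** i)
            self.blocks.append(
                ResNeXtBlock(c_in, c_out, cfg.cardinality, rng))
            c_in = c_out
        self.head = Linear(c_in, cfg.n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return self.head(x.global_avg_pool())

    def forward_with_activations(self, x: Tensor
                                 ) -> tuple[Tensor, list[Tensor]]:
        acts = []
        for block in self.blocks:
            x = block(x)
            acts.append(x)
        return self.head(x.global_avg_pool()), acts

    def forward_from(self, layer: int, activation: np.ndarray) -> Tensor:
        """Recompute the logits starting from a given layer's activation.

        Used by the finite-difference oracle for activation gradients.
        """
        x = Tensor(activation)
        for block in self.blocks[layer + 1:]:
            x = block(x)
        return self.head(x.global_avg_pool())


@dataclass
class FeatureMapStack:
    """Per-layer activations and class-score gradients of the backbone."""

    activations: list[np.ndarray]   # each (C_l, H_l, W_l)
    gradients: list[np.ndarray]     # same shapes; d(score_k)/d(activation)
    selected_class: int
    logits: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        for a, g in zip(self.activations, self.gradients):
            if a.shape != g.shape:
                raise ShapeError("activation/gradient shape mismatch")
            if not (np.isfinite(a).all() and np.isfinite(g).all()):
                raise ValueError("non-finite values in feature map stack")

    @property
    def n_layers(self) -> int:
        return len(self.activations)


def build_backbone(cfg: BackboneConfig) -> ResNeXtBackbone:
    """Construct a backbone with deterministic initialization."""
    return ResNeXtBackbone(cfg)


def image_to_tensor(image: np.ndarray) -> Tensor:
    """(H, W, 3) or (H, W) float image -> (1, 3, H, W) tensor."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ShapeError(f"expected (H, W, 3) image, got {arr.shape}")
    return Tensor(arr.transpose(2, 0, 1)[None])


def collect(backbone: ResNeXtBackbone, image: np.ndarray,
            class_selector: int | str = "argmax") -> FeatureMapStack:
    """Forward + backward pass recording per-layer activation gradients.

    The gradient at each layer is the derivative of the selected class
    logit with respect to that layer's activation map.
    """
    x = image_to_tensor(image)
    if x.shape[-1] != backbone.cfg.input_size:
        raise ShapeError(
            f"image size {x.shape[-2:]} does not match backbone input "
            f"size {backbone.cfg.input_size}")
    backbone.zero_grad()
    logits, acts = backbone.forward_with_activations(x)
    if class_selector == "argmax":
        k = int(np.argmax(logits.data[0]))
    else:
        k = int(class_selector)
        if not 0 <= k < backbone.cfg.n_classes:
            raise ShapeError(f"class index {k} out of range")
    grad = np.zeros_like(logits.data)
    grad[0, k] = 1.0
    logits.backward(grad)
    return FeatureMapStack(
        activations=[a.data[0].copy() for a in acts],
        gradients=[(a.grad[0].copy() if a.grad is not None
                    else np.zeros_like(a.data[0])) for a in acts],
        selected_class=k,
        logits=logits.data[0].copy())
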