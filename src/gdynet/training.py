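"""Joint training: alternating minimization of the two task losses.

The objective is the mean over the training set of a segmentation loss
plus a classification loss,

    min_theta  (1/N) * sum_i [ L_seg(F_theta(x_i), y_i) + L_cls(s_i, c_i) ],

optimized by SGD with momentum and an L2 penalty, *alternating* between
the two losses at mini-batch granularity: odd iterations (1st, 3rd, ...)
step on the segmentation loss only, even iterations on the classification
loss only, so over any full epoch the two step counts differ by at most
one.  A joint mode (single step on the summed loss) is available for
ablation.

L_seg is the mean per-pixel binary cross-entropy between the predicted
disc probability map and the ground-truth mask, scaled by 1/sigma with
sigma in (0, 1] the segmentation loss weight.  A literal weighted-MSE
variant ((1 - y) * (y - p)^2, foreground term suppressed) is kept behind
``seg_loss_literal`` for comparison only - it carries no foreground
signal and is not used by default.  L_cls is binary cross-entropy on the
scalar class score.  Probabilities are clipped at 1e-7 before logs.

The learning rate follows a step schedule: lr0 divided by
``lr_decay_factor`` after every ``lr_decay_period`` epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DomainError, ShapeError, \
    ValidationError
from .io import DatasetManifest, load_image, load_mask
from .metrics import dice
from .model import GDYNet
from .nn import SGDM, Tensor

__all__ = ["TrainConfig", "TrainHistory", "seg_loss", "seg_loss_literal",
           "cls_loss", "lr_at", "train", "load_split_arrays",
           "predict_batches"]

_CLIP = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 100
    batch_size: int = 128
    lr0: float = 0.001
    momentum: float = 0.9
    l2: float = 0.001
    lr_decay_factor: float = 2.0
    lr_decay_period: int = 20
    sigma: float = 0.5
    seed: int = 0
    mode: str = "alternating"       # or "joint"

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ConfigurationError("lr0 must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must lie in [0, 1)")
        if not 0.0 < self.sigma <= 1.0:
            raise ConfigurationError("sigma must lie in (0, 1]")
        if self.lr_decay_factor <= 1.0:
            raise ConfigurationError("lr_decay_factor must be > 1")
        if self.lr_decay_period < 1:
            raise ConfigurationError("lr_decay_period must be >= 1")
        if self.mode not in ("alternating", "joint"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        self.epochs.append(record)

    def final(self) -> dict:
        return self.epochs[-1]

    def to_records(self) -> list[dict]:
        return list(self.epochs)


def _bce(p: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeError(f"prediction {p.shape} vs target {t.shape}")
    pc = p.clip(_CLIP, 1.0 - _CLIP)
    return -(Tensor(t) * pc.log() + Tensor(1.0 - t)
             * (1.0 - pc).log()).mean()


def seg_loss(seg_prob: Tensor | np.ndarray, gt_mask: np.ndarray,
             sigma: float) -> Tensor:
    """Mean per-pixel BCE between probability map and mask, scaled 1/sigma."""
    if not 0.0 < sigma <= 1.0:
        raise DomainError("sigma must lie in (0, 1]")
    p = seg_prob if isinstance(seg_prob, Tensor) else Tensor(seg_prob)
    return _bce(p, gt_mask) * (1.0 / sigma)


def seg_loss_literal(seg_prob: Tensor | np.ndarray, gt_mask: np.ndarray,
                     sigma: float) -> Tensor:
    """Background-weighted squared error (1-y)*(y-p)^2 / sigma (mean)."""
    if not 0.0 < sigma <= 1.0:
        raise DomainError("sigma must lie in (0, 1]")
    p = seg_prob if isinstance(seg_prob, Tensor) else Tensor(seg_prob)
    t = np.asarray(gt_mask, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeError(f"prediction {p.shape} vs target {t.shape}")
    return ((Tensor(t) - p) ** 2 * Tensor(1.0 - t)).mean() * (1.0 / sigma)


def cls_loss(class_score: Tensor | np.ndarray, label) -> Tensor:
    """Binary cross-entropy on the scalar (or batched) class score."""
    p = class_score if isinstance(class_score, Tensor) else Tensor(class_score)
    y = np.asarray(label, dtype=np.float64).reshape(p.shape)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DomainError("labels must be 0 or 1")
    return _bce(p, y)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: lr0 / factor^floor(epoch / period)."""
    if epoch < 0:
        raise DomainError("epoch must be >= 0")
    return cfg.lr0 / cfg.lr_decay_factor ** (epoch // cfg.lr_decay_period)


def load_split_arrays(manifest: DatasetManifest, split: str,
                      require_labels: bool = True
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load (images, masks, labels) arrays for one manifest split."""
    rows = manifest.subset(split).rows
    problems = [f"row {i} ({r.image_path}): missing "
                + ("mask" if not r.disc_mask_path else "label")
                for i, r in enumerate(rows)
                if not r.disc_mask_path or (require_labels
                                            and r.label is None)]
    if problems:
        raise ValidationError("; ".join(problems))
    images = np.stack([load_image(r.image_path).transpose(2, 0, 1)
                       for r in rows])
    masks = np.stack([load_mask(r.disc_mask_path) for r in rows])
    labels = np.array([-1 if r.label is None else r.label for r in rows])
    return images, masks, labels


def predict_batches(model: GDYNet, images: np.ndarray, batch_size: int = 16
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Inference over a (N, 3, H, W) array; returns (seg_probs, scores).

    Runs in eval mode (normalization uses running statistics), restoring
    the previous mode afterwards.
    """
    was_training = getattr(model.feat_norm, "training", False)
    model.set_training(False)
    try:
        probs, scores = [], []
        for i in range(0, len(images), batch_size):
            out = model(Tensor(images[i:i + batch_size]))
            probs.append(out.seg_prob.data)
            scores.append(out.class_score.data)
        return np.concatenate(probs), np.concatenate(scores)
    finally:
        model.set_training(was_training)


def train(model: GDYNet, manifest: DatasetManifest, cfg: TrainConfig,
          val_split: str | None = "test",
          checkpoint_dir: str | Path | None = None
          ) -> tuple[GDYNet, TrainHistory]:
    """Train the joint model on the manifest's ``train`` split.

    Deterministic under (model seed, cfg.seed, manifest order).  Returns
    the trained model and a per-epoch history; if ``val_split`` names a
    non-empty split with masks and labels, held-out Dice and accuracy are
    recorded each epoch.
    """
    images, masks, labels = load_split_arrays(manifest, "train")
    if len(images) == 0:
        raise ValidationError("manifest has no training rows")
    val = None
    if val_split and len(manifest.subset(val_split)):
        val = load_split_arrays(manifest, val_split)

    rng = np.random.default_rng(cfg.seed)
    model.set_training(True)
    opt = SGDM(model, lr=cfg.lr0, momentum=cfg.momentum, l2=cfg.l2)
    history = TrainHistory()
    step = 0   # global iteration counter; first iteration steps on L_seg
    n = len(images)
    for epoch in range(cfg.max_epochs):
        opt.lr = lr_at(epoch, cfg)
        order = rng.permutation(n)
        seg_losses, cls_losses = [], []
        n_seg_steps = n_cls_steps = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = model(Tensor(images[idx]))
            l_seg = seg_loss(out.seg_prob, masks[idx], cfg.sigma)
            l_cls = cls_loss(out.class_score, labels[idx])
            seg_losses.append(float(l_seg.data))
            cls_losses.append(float(l_cls.data))
            opt.zero_grad()
            if cfg.mode == "joint":
                (l_seg + l_cls).backward()
                n_seg_steps += 1
                n_cls_steps += 1
            elif step % 2 == 0:
                l_seg.backward()
                n_seg_steps += 1
            else:
                l_cls.backward()
                n_cls_steps += 1
            opt.step()
            step += 1
        record = {
            "epoch": epoch,
            "seg_loss": float(np.mean(seg_losses)),
            "cls_loss": float(np.mean(cls_losses)),
            "objective": float(np.mean(seg_losses) + np.mean(cls_losses)),
            "lr": lr_at(epoch, cfg),
            "seg_steps": n_seg_steps,
            "cls_steps": n_cls_steps,
        }
        if val is not None:
            v_imgs, v_masks, v_labels = val
            probs, scores = predict_batches(model, v_imgs,
                                            min(cfg.batch_size, 16))
            dices = [dice(probs[i] >= 0.5, v_masks[i])
                     for i in range(len(v_imgs))]
            record["val_dice"] = float(np.mean(dices))
            record["val_accuracy"] = float(
                np.mean((scores > 0.5).astype(int) == v_labels))
        history.append(**record)
        from .model import calibrate_feature_norm
        calibrate_feature_norm(model, images, min(cfg.batch_size, 16))
        if checkpoint_dir is not None:
            boundary = (epoch + 1) % cfg.lr_decay_period == 0
            best = val is not None and record.get("val_dice", 0.0) >= max(
                (r.get("val_dice", -1.0) for r in history.epochs), default=-1)
            if boundary or best:
                from .checkpoint import save_model
                name = f"epoch_{epoch:03d}.npz" if boundary else "best.npz"
                save_model(model, Path(checkpoint_dir) / name)
    model.set_training(False)
    return model, history
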