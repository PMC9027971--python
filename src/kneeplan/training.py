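"""Optimization of the multi-task objective.

The composite objective is the weighted sum over tasks ``sum_t w_t L_t``
with Soft-Dice + binary cross-entropy for segmentation and per-pixel MSE
for keypoint/line heatmap regression. Weights are either uniform
(``w_t = 1``) or adapted online with GradNorm (asymmetry ``alpha = 1``),
which levels the per-task training rates by matching each task's gradient
magnitude at the last shared layer to the mean magnitude scaled by the
task's relative inverse training rate.

Optimization follows a cyclical learning-rate policy: learning rate and
Nesterov momentum anneal linearly and inversely between their bounds
(lr 0.001..0.1, momentum 0.8..0.9) over a full cycle of 360 update
iterations, with batch size 2 and an L2 penalty of 5e-5. An RMSProp
variant (single x0.1 decay at epoch 350) is available for harder,
intra-operative-style data. Model selection is the epoch minimizing the
*unweighted* composite validation loss sum_t L_t.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .decoding import FeatureSet
from .encoding import DEFAULT_SIGMA, encode_keypoint, encode_line, rasterize_mask
from .geometry import Keypoint, PolygonRegion, Polyline
from .model import MultiTaskModel, TaskKind, TaskSpec
from .nn import BatchNorm2d, NesterovSGD, RMSProp


class OptimizerKind(str, Enum):
    nesterov_clr = "nesterov_clr"
    rmsprop_step = "rmsprop_step"


class WeightingKind(str, Enum):
    uniform = "uniform"
    gradnorm = "gradnorm"


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 400
    batch_size: int = 2
    optimizer: OptimizerKind = OptimizerKind.nesterov_clr
    lr_min: float = 0.001
    lr_max: float = 0.1
    momentum_min: float = 0.8
    momentum_max: float = 0.9
    cycle_len: int = 360
    rmsprop_lr: float = 0.001
    rmsprop_decay_epoch: int = 350
    rmsprop_decay_factor: float = 0.1
    weight_decay: float = 0.00005
    weighting: WeightingKind = WeightingKind.uniform
    gradnorm_alpha: float = 1.0
    gradnorm_lr: float = 0.025  # step size for the task-weight updates
    gradnorm_init_step: int = 1  # record reference losses after this update
    sigma: float = DEFAULT_SIGMA
    augment: bool = True
    # online augmentation protocol (defaults: full clinical-scale ranges)
    augment_rotation_deg: float = 45.0
    augment_scale: tuple[float, float] = (0.8, 1.2)
    augment_flip_p: float = 0.5
    augment_shear_p: float = 0.5
    augment_shear_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "optimizer", OptimizerKind(self.optimizer))
        object.__setattr__(self, "weighting", WeightingKind(self.weighting))
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if not self.momentum_min < self.momentum_max:
            raise ValueError("momentum_min must be < momentum_max")
        if min(self.epochs, self.batch_size, self.cycle_len) <= 0:
            raise ValueError("epochs, batch_size and cycle_len must be positive")


@dataclass(frozen=True)
class TaskWeights:
    w: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.w.values()):
            raise ValueError(f"task weights must be positive: {self.w}")

    @classmethod
    def uniform(cls, names: Iterable[str]) -> "TaskWeights":
        return cls(w={n: 1.0 for n in names})

    def total(self) -> float:
        return float(sum(self.w.values()))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalize_intensity(img: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]: ``(x - min) / (max - min)``.

    A constant image maps to all zeros (with a warning) to guard the
    division.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant image: min-max normalization returns zeros", stacklevel=2)
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


@dataclass(frozen=True)
class FrameMap:
    """Forward/inverse coordinate map of the resize-and-pad preprocessing."""

    scale: float

    def forward(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) * self.scale

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) / self.scale


def _map_feature_affine(feature, lin: np.ndarray, t: np.ndarray):
    """Apply a general affine (2x2 linear + translation) to a feature."""
    if isinstance(feature, Keypoint):
        x, y = np.asarray([feature.x, feature.y]) @ lin.T + t
        return replace(feature, x=float(x), y=float(y))
    if isinstance(feature, Polyline):
        return replace(feature, points=feature.points @ lin.T + t)
    if isinstance(feature, PolygonRegion):
        return PolygonRegion(
            shell=feature.shell @ lin.T + t,
            holes=tuple(h @ lin.T + t for h in feature.holes),
            label=feature.label,
        )
    raise TypeError(type(feature).__name__)


def _map_featureset(features: FeatureSet, lin: np.ndarray, t: np.ndarray) -> FeatureSet:
    out = FeatureSet(missing=dict(features.missing), provenance=dict(features.provenance))
    for pool in (features.keypoints, features.lines, features.regions):
        for feat in pool.values():
            out.add(feat := _map_feature_affine(feat, lin, t), features.provenance.get(feat.label, "automatic"))
    return out


def geometric_preprocess(
    img: np.ndarray, features: FeatureSet | None = None, target: int = 256
) -> tuple[np.ndarray, FeatureSet | None, FrameMap]:
    """Bring an image to ``target x target`` by isotropic bicubic resampling
    and zero padding (right/bottom), preserving the aspect ratio.

    Geometry is mapped by the pure scale ``s = target / max(H, W)`` (no
    offset, since padding is applied on the right/bottom only); the returned
    :class:`FrameMap` restores original-frame coordinates.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    s = target / max(h, w)
    h2, w2 = int(round(h * s)), int(round(w * s))
    if (h2, w2) == (h, w):
        resized = img
    else:
        resized = sktransform.resize(
            img, (h2, w2), order=3, anti_aliasing=s < 1.0, preserve_range=True, mode="constant"
        )
    canvas = np.zeros((target, target), dtype=float)
    canvas[:h2, :w2] = resized
    fmap = FrameMap(scale=s)
    mapped = None
    if features is not None:
        mapped = _map_featureset(features, np.eye(2) * s, np.zeros(2))
    return canvas, mapped, fmap


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentParams:
    flip: bool = False
    shear_deg: float = 0.0
    rotation_deg: float = 0.0
    scale: float = 1.0


def draw_augment_params(rng: np.random.Generator, cfg: "TrainConfig | None" = None) -> AugmentParams:
    """Sample the augmentation protocol. Defaults: light shear in [-2, 2]
    degrees (p = 0.5), horizontal flip (p = 0.5), in-plane rotation in
    [-45, 45] degrees (p = 1) and scaling in [0.8, 1.2] (p = 1); the ranges
    are config-exposed so reduced-scale protocols can narrow them."""
    rot_max = cfg.augment_rotation_deg if cfg else 45.0
    scale_rng = cfg.augment_scale if cfg else (0.8, 1.2)
    flip_p = cfg.augment_flip_p if cfg else 0.5
    shear_p = cfg.augment_shear_p if cfg else 0.5
    shear_max = cfg.augment_shear_deg if cfg else 2.0
    flip = rng.random() < flip_p
    shear = rng.uniform(-shear_max, shear_max) if rng.random() < shear_p else 0.0
    rot = rng.uniform(-rot_max, rot_max)
    scale = rng.uniform(*scale_rng)
    return AugmentParams(flip=flip, shear_deg=shear, rotation_deg=rot, scale=scale)


def _augment_matrix(params: AugmentParams, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a = np.radians(params.rotation_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    sh = np.array([[1.0, np.tan(np.radians(params.shear_deg))], [0.0, 1.0]])
    flip = np.diag([-1.0, 1.0]) if params.flip else np.eye(2)
    lin = rot @ (params.scale * np.eye(2)) @ sh @ flip
    center = np.array([cx, cy])
    t = center - lin @ center
    return lin, t


def augment(
    img: np.ndarray, features: FeatureSet, rng: np.random.Generator, params: AugmentParams | None = None
) -> tuple[np.ndarray, FeatureSet]:
    """Warp the image and map the numeric ground truth through the exact same
    affine (labels are transformed in coordinate space, never through raster
    interpolation). Spatial encodings must be generated only afterwards."""
    if params is None:
        params = draw_augment_params(rng)
    lin, t = _augment_matrix(params, img.shape)
    hom = np.eye(3)
    hom[:2, :2] = lin
    hom[:2, 2] = t
    tform = sktransform.AffineTransform(matrix=hom)
    warped = sktransform.warp(img.astype(float), tform.inverse, order=1, preserve_range=True)
    return warped, _map_featureset(features, lin, t)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_EPS_DICE = 1.0
_EPS_BCE = 1e-7


def _as4d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[None] if a.ndim == 3 else a


def task_loss(task: TaskSpec, pred: np.ndarray, target: np.ndarray) -> float:
    """Per-task loss: ``(1 - softDice) + BCE`` (channel means) for
    segmentation, per-pixel MSE for keypoint/line heatmaps."""
    loss, _ = task_loss_and_grad(task, pred, target, need_grad=False)
    return loss


def task_loss_and_grad(
    task: TaskSpec, pred: np.ndarray, target: np.ndarray, need_grad: bool = True
) -> tuple[float, np.ndarray | None]:
    p, t = _as4d(pred), _as4d(target)
    if p.shape != t.shape:
        raise ValueError(f"pred/target shape mismatch: {p.shape} vs {t.shape}")
    n, c = p.shape[0], p.shape[1]
    if task.kind in (TaskKind.keypoint, TaskKind.line):
        diff = p - t
        loss = float(np.mean(diff * diff))
        grad = (2.0 / diff.size) * diff if need_grad else None
        return loss, grad
    # segmentation: soft Dice (eps = 1) + BCE, each averaged over samples/channels
    pc = np.clip(p, _EPS_BCE, 1.0 - _EPS_BCE)
    axes = (2, 3)
    inter = (pc * t).sum(axis=axes)
    psum = pc.sum(axis=axes)
    tsum = t.sum(axis=axes)
    num = 2.0 * inter + _EPS_DICE
    den = psum + tsum + _EPS_DICE
    dice = num / den
    bce_px = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc))
    loss = float(np.mean(1.0 - dice) + np.mean(bce_px))
    if not need_grad:
        return loss, None
    npx = p.shape[2] * p.shape[3]
    ddice = -(2.0 * t * den[..., None, None] - num[..., None, None]) / (den[..., None, None] ** 2)
    dbce = (pc - t) / (pc * (1.0 - pc))
    grad = ddice / (n * c) + dbce / (n * c * npx)
    return loss, grad


def composite_loss(losses: dict[str, float], weights: TaskWeights) -> float:
    """Weighted linear combination ``sum_t w_t L_t``."""
    missing = set(losses) - set(weights.w)
    if missing:
        raise KeyError(f"missing weights for tasks: {sorted(missing)}")
    return float(sum(weights.w[k] * v for k, v in losses.items()))


# ---------------------------------------------------------------------------
# Schedules and GradNorm
# ---------------------------------------------------------------------------


def clr_schedule(iteration: int, cfg: TrainConfig) -> tuple[float, float]:
    """Triangular cyclical schedule: the learning rate rises linearly from
    ``lr_min`` to ``lr_max`` over the first half-cycle and falls back over
    the second; momentum anneals inversely (high when the learning rate is
    low). Periodic with period ``cycle_len``."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    phase = iteration % cfg.cycle_len
    half = cfg.cycle_len / 2.0
    frac = phase / half if phase <= half else (cfg.cycle_len - phase) / half
    lr = cfg.lr_min + frac * (cfg.lr_max - cfg.lr_min)
    momentum = cfg.momentum_max - frac * (cfg.momentum_max - cfg.momentum_min)
    return lr, momentum


def gradnorm_step(
    weights: TaskWeights,
    current_losses: dict[str, float],
    initial_losses: dict[str, float],
    shared_layer_grad_norms: dict[str, float],
    alpha: float = 1.0,
    lr: float = 0.025,
) -> TaskWeights:
    """One GradNorm update of the task weights.

    ``shared_layer_grad_norms`` holds ``G_t = |grad of (w_t L_t) at the
    shared layer|``. With relative inverse training rates
    ``r_t = (L_t / L_t(0)) / mean(.)`` the weights take a gradient step on
    ``sum_t |G_t - mean(G) * r_t^alpha|`` (the target treated as constant)
    and are renormalized so that ``sum_t w_t = T``. Non-finite gradient
    norms skip the update with a warning.
    """
    names = sorted(weights.w)
    g = np.array([shared_layer_grad_norms[n] for n in names], dtype=float)
    if not np.all(np.isfinite(g)):
        warnings.warn("non-finite gradient norms; skipping GradNorm update", stacklevel=2)
        return weights
    w = np.array([weights.w[n] for n in names], dtype=float)
    cur = np.array([current_losses[n] for n in names], dtype=float)
    init = np.array([max(initial_losses[n], 1e-12) for n in names], dtype=float)
    ltilde = cur / init
    r = ltilde / max(float(ltilde.mean()), 1e-12)
    target = g.mean() * np.power(r, alpha)
    # G_t is linear in w_t (G_t = w_t * |grad of L_t|), so dG_t/dw_t = G_t / w_t
    grad_w = np.sign(g - target) * (g / np.maximum(w, 1e-12))
    w_new = np.maximum(w - lr * grad_w, 1e-3)
    w_new *= len(names) / w_new.sum()
    return TaskWeights(w=dict(zip(names, w_new)))


# ---------------------------------------------------------------------------
# Target encoding
# ---------------------------------------------------------------------------


def build_targets(
    features: FeatureSet, tasks: Sequence[TaskSpec], shape: tuple[int, int], sigma: float
) -> dict[str, np.ndarray]:
    """Encode a feature set into per-task target stacks.

    A feature that is absent (or a keypoint pushed outside the frame by
    augmentation, i.e. an invisible landmark) yields an all-zero channel.
    """
    targets: dict[str, np.ndarray] = {}
    h, w = shape
    for task in tasks:
        labels = task.channel_labels or tuple(f"{task.name}_{i}" for i in range(task.n_channels))
        channels = np.zeros((task.n_channels, h, w), dtype=float)
        for i, label in enumerate(labels):
            if task.kind == TaskKind.segmentation:
                region = features.regions.get(label)
                if region is not None:
                    channels[i] = rasterize_mask([region], shape).data[0]
            elif task.kind == TaskKind.keypoint:
                kp = features.keypoints.get(label)
                if kp is not None and kp.in_domain(shape):
                    channels[i] = encode_keypoint(kp, shape, sigma=sigma).grid
            else:
                line = features.lines.get(label)
                if line is not None:
                    channels[i] = encode_line(line, shape, sigma=sigma).grid
        targets[task.name] = channels
    return targets


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: MultiTaskModel  # restored to the selected (best) epoch
    best_epoch: int
    history: pd.DataFrame
    final_weights: TaskWeights


def _snapshot(model: MultiTaskModel) -> tuple[list[np.ndarray], list[tuple[np.ndarray, np.ndarray]]]:
    params = [p.data.copy() for p in model.parameters()]
    bn = [
        (m.running_mean.copy(), m.running_var.copy())
        for m in model.modules()
        if isinstance(m, BatchNorm2d)
    ]
    return params, bn


def _restore(model: MultiTaskModel, snap) -> None:
    params, bn = snap
    model.load_state_arrays(params)
    for m, (mean, var) in zip(
        (m for m in model.modules() if isinstance(m, BatchNorm2d)), bn
    ):
        m.running_mean = mean.copy()
        m.running_var = var.copy()


def _prepare_sample(sample, cfg: TrainConfig, size: int, rng=None, do_augment=False):
    img, feats = sample.image, sample.features
    if do_augment:
        img, feats = augment(img, feats, rng, params=draw_augment_params(rng, cfg))
    img, feats, _ = geometric_preprocess(img, feats, target=size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        img = normalize_intensity(img)
    return img, feats


def train(model: MultiTaskModel, dataset, cfg: TrainConfig) -> TrainResult:
    """Run the training loop and return the checkpoint of the epoch with the
    minimum unweighted composite validation loss, plus the full history.

    ``dataset`` is either a ``(train, val)`` pair of sample sequences or an
    object with ``train``/``val`` attributes; each sample exposes ``image``
    (H x W raster) and ``features`` (:class:`FeatureSet`).
    """
    if isinstance(dataset, (tuple, list)) and len(dataset) == 2:
        train_samples, val_samples = dataset
    else:
        train_samples, val_samples = dataset.train, dataset.val
    train_samples, val_samples = list(train_samples), list(val_samples)
    if not train_samples or not val_samples:
        raise ValueError("both train and validation splits must be non-empty")

    tasks = model.config.tasks
    size = model.config.input_size
    rng = np.random.default_rng(cfg.seed)
    params = list(model.parameters())
    if cfg.optimizer == OptimizerKind.nesterov_clr:
        opt = NesterovSGD(params, weight_decay=cfg.weight_decay)
    else:
        opt = RMSProp(params, weight_decay=cfg.weight_decay)

    weights = TaskWeights.uniform([t.name for t in tasks])
    use_gradnorm = cfg.weighting == WeightingKind.gradnorm
    initial_losses: dict[str, float] | None = None

    # pre-encode validation batches once (no augmentation)
    val_prepared = [_prepare_sample(s, cfg, size) for s in val_samples]
    val_targets = [build_targets(f, tasks, (size, size), cfg.sigma) for _, f in val_prepared]

    history_rows = []
    best = (np.inf, -1)
    best_snap = None
    iteration = 0

    for epoch in range(1, cfg.epochs + 1):
        model.set_train(True)
        order = rng.permutation(len(train_samples))
        epoch_losses = {t.name: 0.0 for t in tasks}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs, target_list = [], []
            for i in idx:
                img, feats = _prepare_sample(
                    train_samples[i], cfg, size, rng=rng, do_augment=cfg.augment
                )
                imgs.append(img)
                target_list.append(build_targets(feats, tasks, (size, size), cfg.sigma))
            x = np.stack(imgs)[:, None]
            targets = {
                t.name: np.stack([tl[t.name] for tl in target_list]) for t in tasks
            }
            outs = model.forward(x)
            model.zero_grad()
            losses: dict[str, float] = {}
            d_outs: dict[str, np.ndarray] = {}
            for t in tasks:
                loss, grad = task_loss_and_grad(t, outs[t.name], targets[t.name])
                losses[t.name] = loss
                d_outs[t.name] = weights.w[t.name] * grad
            norms = model.backward(d_outs, collect_gradnorm=use_gradnorm)
            if cfg.optimizer == OptimizerKind.nesterov_clr:
                lr, momentum = clr_schedule(iteration, cfg)
                opt.step(lr, momentum)
            else:
                lr = cfg.rmsprop_lr * (
                    cfg.rmsprop_decay_factor if epoch > cfg.rmsprop_decay_epoch else 1.0
                )
                opt.step(lr)
            iteration += 1
            if use_gradnorm:
                if iteration == cfg.gradnorm_init_step:
                    initial_losses = dict(losses)
                if initial_losses is not None:
                    weights = gradnorm_step(
                        weights,
                        losses,
                        initial_losses,
                        norms,
                        alpha=cfg.gradnorm_alpha,
                        lr=cfg.gradnorm_lr,
                    )
            for k, v in losses.items():
                epoch_losses[k] += v
            n_batches += 1

        # validation: unweighted composite loss with frozen statistics
        model.set_train(False)
        val_losses = {t.name: 0.0 for t in tasks}
        for (img, _), tgt in zip(val_prepared, val_targets):
            outs = model.forward(img[None, None])
            for t in tasks:
                val_losses[t.name] += task_loss(t, outs[t.name], tgt[t.name][None])
        val_losses = {k: v / len(val_prepared) for k, v in val_losses.items()}
        val_total = float(sum(val_losses.values()))
        row = {"epoch": epoch, "val_total": val_total, "lr": lr}
        for t in tasks:
            row[f"train_{t.name}"] = epoch_losses[t.name] / max(n_batches, 1)
            row[f"val_{t.name}"] = val_losses[t.name]
            row[f"w_{t.name}"] = weights.w[t.name]
        history_rows.append(row)
        if val_total < best[0]:
            best = (val_total, epoch)
            best_snap = _snapshot(model)

    if best_snap is not None:
        _restore(model, best_snap)
    history = pd.DataFrame(history_rows)
    return TrainResult(model=model, best_epoch=best[1], history=history, final_weights=weights)
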