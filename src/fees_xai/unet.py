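"""2D U-Net for multi-structure segmentation, with its training loop.

The network is an encoder–decoder with skip connections, zero-padded
convolutions (output resolution equals input resolution), batch
normalization, PReLU activations and dropout, and per-channel sigmoid
heads.  The three output channels (glottis ROI, vocal cords, aspiration)
are independent: the classes overlap — aspiration lies inside the ROI — so
mutually exclusive softmax labeling would be wrong.

Training minimizes a soft Dice loss with Adam, draws stratified patches,
and applies Jaccard-based early stopping: every ``val_interval`` iterations
the per-class Jaccard score against the validation references is computed,
and after ``patience`` validations without an improvement of the mean
Jaccard the training stops, returning the network state with the highest
validation score.

Runs on NumPy (im2col convolutions with explicit backprop); intended scale
is small-to-moderate nets on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import FrameImage, ReferenceAnnotation
from .layers import (
    Adam,
    BatchNorm2D,
    Conv2D,
    Dropout2D,
    Layer,
    MaxPool2D,
    Param,
    PReLU,
    Sigmoid,
    UpsampleNearest2D,
)
from .metrics import jaccard
from .preprocess import PatchSampler

__all__ = [
    "NetConfig",
    "TrainConfig",
    "TrainHistory",
    "ValidationRecord",
    "EarlyStopper",
    "UNet",
    "build_net",
    "dice_loss",
    "soft_dice_loss_and_grad",
    "train",
    "predict_frame",
    "save_model",
    "load_model",
]

CLASS_NAMES = ("glottis_roi", "vocal_cords", "aspiration")


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``base_filters`` is the channel count of the first encoder level;
    filters double per level, so the deepest stage has
    ``base_filters · 2^(depth−1)`` channels.
    """

    base_filters: int = 32
    depth: int = 4
    dropout_rate: float = 0.1
    n_classes: int = 3
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.base_filters < 1:
            raise ValueError("base_filters must be ≥ 1")
        if self.depth < 2:
            raise ValueError("depth must be ≥ 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def divisor(self) -> int:
        """Input spatial sizes must be divisible by this (one pooling per level)."""
        return 2 ** (self.depth - 1)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    val_interval: int = 500
    patience: int = 15
    max_iterations: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "val_interval", "patience", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ValidationRecord:
    iteration: int
    val_loss: float
    jaccard_per_class: dict[str, float]
    mean_jaccard: float


@dataclass
class TrainHistory:
    losses: list[tuple[int, float]] = field(default_factory=list)
    validations: list[ValidationRecord] = field(default_factory=list)
    best_iteration: int | None = None

    def best_mean_jaccard(self) -> float:
        return max((v.mean_jaccard for v in self.validations), default=float("nan"))

    def save_csv(self, path: str | Path) -> Path:
        import pandas as pd

        rows = [
            {
                "iteration": v.iteration,
                "val_loss": v.val_loss,
                "mean_jaccard": v.mean_jaccard,
                **{f"jaccard_{k}": s for k, s in v.jaccard_per_class.items()},
            }
            for v in self.validations
        ]
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(p, index=False)
        return p

    def plot(self, path: str | Path) -> Path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax1 = plt.subplots(figsize=(7, 4))
        if self.losses:
            its, ls = zip(*self.losses)
            ax1.plot(its, ls, color="C0", alpha=0.6, label="training loss")
        if self.validations:
            ax1.plot(
                [v.iteration for v in self.validations],
                [v.val_loss for v in self.validations],
                color="C3",
                label="validation loss",
            )
        ax1.set_xlabel("iteration")
        ax1.set_ylabel("Dice loss")
        ax2 = ax1.twinx()
        for k in CLASS_NAMES:
            ax2.plot(
                [v.iteration for v in self.validations],
                [v.jaccard_per_class.get(k, np.nan) for v in self.validations],
                linestyle="--",
                label=f"Jaccard {k}",
            )
        ax2.plot(
            [v.iteration for v in self.validations],
            [v.mean_jaccard for v in self.validations],
            color="c",
            label="mean Jaccard",
        )
        if self.best_iteration is not None:
            ax1.axvline(self.best_iteration, color="k", linewidth=0.8)
        ax2.set_ylabel("validation Jaccard")
        fig.legend(loc="lower center", ncol=3, fontsize=7)
        fig.tight_layout(rect=(0, 0.12, 1, 1))
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p


class EarlyStopper:
    """Stop after ``patience`` validations without a strictly better score."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best_score = -np.inf
        self.best_step: int | None = None
        self.bad = 0

    def update(self, score: float, step: int) -> bool:
        """Record one validation score; returns True when training should stop."""
        if score > self.best_score:
            self.best_score = score
            self.best_step = step
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def buffers(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend(l.state().values())
        return out

    def set_buffers(self, values: list[np.ndarray]) -> int:
        i = 0
        for l in self.layers:
            st = l.state()
            for key in st:
                setattr(l, key, values[i].copy())
                i += 1
        return i


def _conv_block(c_in: int, c_out: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2D(c_in, c_out, 3, rng),
        BatchNorm2D(c_out),
        PReLU(c_out),
        Conv2D(c_out, c_out, 3, rng),
        BatchNorm2D(c_out),
        PReLU(c_out),
    )


class UNet:
    """Encoder–decoder segmentation network with skip connections."""

    def __init__(self, config: NetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng([seed, 97])
        drop_rng = np.random.default_rng([seed, 98])
        f, d = config.base_filters, config.depth
        ch = [f * 2**i for i in range(d)]
        self.enc = [
            _conv_block(config.in_channels if i == 0 else ch[i - 1], ch[i], rng) for i in range(d)
        ]
        self.pools = [MaxPool2D() for _ in range(d - 1)]
        self.up = [
            Sequential(
                UpsampleNearest2D(),
                Conv2D(ch[j + 1], ch[j], 3, rng),
                BatchNorm2D(ch[j]),
                PReLU(ch[j]),
            )
            for j in range(d - 1)
        ]
        self.dec = [_conv_block(2 * ch[j], ch[j], rng) for j in range(d - 1)]
        self.dropouts = [Dropout2D(config.dropout_rate, drop_rng) for _ in range(d - 1)]
        self.head = Conv2D(ch[0], config.n_classes, 1, rng)
        self.out_act = Sigmoid()
        self._skip_channels = ch

    # -- parameter plumbing -------------------------------------------------

    def _modules(self) -> list[Layer]:
        mods: list[Layer] = []
        mods.extend(self.enc)
        mods.extend(self.up)
        mods.extend(self.dec)
        mods.append(self.head)
        return mods

    def params(self) -> list[Param]:
        return [p for m in self._modules() for p in m.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def snapshot(self) -> dict:
        values = [p.value.copy() for p in self.params()]
        buffers = []
        for m in self._modules():
            if isinstance(m, Sequential):
                buffers.extend(b.copy() for b in m.buffers())
        return {"params": values, "buffers": buffers}

    def restore(self, snap: dict) -> None:
        for p, v in zip(self.params(), snap["params"], strict=True):
            p.value = v.copy()
        i = 0
        for m in self._modules():
            if isinstance(m, Sequential):
                n = len(m.buffers())
                m.set_buffers([b for b in snap["buffers"][i : i + n]])
                i += n

    # -- forward / backward -------------------------------------------------

    def _check_size(self, x: np.ndarray) -> None:
        dv = self.config.divisor
        if x.shape[1] % dv or x.shape[2] % dv:
            raise ValueError(
                f"input spatial size {x.shape[1:3]} must be divisible by {dv} "
                f"(depth {self.config.depth}); pad the input first"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """NHWC float input in [0,1] → per-class probability maps (N,H,W,3)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_size(x)
        d = self.config.depth
        skips: list[np.ndarray] = []
        h = x
        for i in range(d):
            h = self.enc[i].forward(h, training)
            if i < d - 1:
                skips.append(h)
                h = self.pools[i].forward(h, training)
        for j in reversed(range(d - 1)):
            h = self.up[j].forward(h, training)
            h = np.concatenate([h, skips[j]], axis=-1)
            h = self.dec[j].forward(h, training)
            h = self.dropouts[j].forward(h, training)
        logits = self.head.forward(h, training)
        return self.out_act.forward(logits, training)

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        d = self.config.depth
        dy = self.out_act.backward(dprob)
        dy = self.head.backward(dy)
        dskips: dict[int, np.ndarray] = {}
        for j in range(d - 1):
            dy = self.dropouts[j].backward(dy)
            dy = self.dec[j].backward(dy)
            c = self._skip_channels[j]
            dskips[j] = dy[..., c:]
            dy = self.up[j].backward(np.ascontiguousarray(dy[..., :c]))
        for i in reversed(range(d)):
            if i < d - 1:
                dy = self.pools[i].backward(dy) + dskips[i]
            dy = self.enc[i].backward(dy)


def build_net(config: NetConfig, seed: int = 0) -> UNet:
    """Construct the network with seeded He-normal weight initialization."""
    return UNet(config, seed=seed)


# ---------------------------------------------------------------------------
# Loss


def soft_dice_loss_and_grad(
    pred: np.ndarray,
    target: np.ndarray,
    eps: float = 1.0,
    channel_axis: int = 1,
) -> tuple[float, np.ndarray]:
    """Soft Dice loss (1 − mean channel Dice) and its gradient w.r.t. pred.

    Per sample and channel: dice = (2 Σ p·t + ε) / (Σ p + Σ t + ε); the
    smoothing ε keeps empty channels well-defined and the gradient bounded.
    Inputs are (C,H,W) or batched with the class channel on ``channel_axis``.
    """
    pred = np.asarray(pred, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    squeeze = pred.ndim == 3
    if squeeze:  # single sample, channel-first
        pred, target = pred[None], target[None]
        channel_axis = 1
    pred_m = np.moveaxis(pred, channel_axis, 1)
    target_m = np.moveaxis(target, channel_axis, 1)
    n, c = pred_m.shape[:2]
    inter = (pred_m * target_m).sum(axis=(2, 3))
    psum = pred_m.sum(axis=(2, 3))
    tsum = target_m.sum(axis=(2, 3))
    num = 2.0 * inter + eps
    den = psum + tsum + eps
    dice_nc = num / den
    loss = 1.0 - float(dice_nc.mean())
    grad_m = -(2.0 * target_m * den[:, :, None, None] - num[:, :, None, None]) / (
        den[:, :, None, None] ** 2 * n * c
    )
    grad = np.moveaxis(grad_m, 1, channel_axis)
    if squeeze:
        grad = grad[0]
    return loss, np.ascontiguousarray(grad, dtype=np.float32)


def dice_loss(
    pred: np.ndarray, target: np.ndarray, eps: float = 1.0, channel_axis: int = 1
) -> float:
    """Soft Dice loss in [0, 1]; 0 for a perfect prediction (as ε → 0)."""
    loss, _ = soft_dice_loss_and_grad(pred, target, eps, channel_axis)
    return loss


# ---------------------------------------------------------------------------
# Inference


def _prepare_input(frame: FrameImage | np.ndarray) -> np.ndarray:
    px = frame.pixels if isinstance(frame, FrameImage) else np.asarray(frame)
    return px.astype(np.float32)[None] / 255.0


def predict_frame(model: UNet, frame: FrameImage | np.ndarray) -> np.ndarray:
    """Per-class probability maps (3×H×W) for one preprocessed frame.

    Pads reflectively to the network's divisibility requirement, runs an
    evaluation-mode forward pass, and crops back to the frame size.
    """
    x = _prepare_input(frame)
    _, h, w, _ = x.shape
    dv = model.config.divisor
    ph = (-h) % dv
    pw = (-w) % dv
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
    maps = model.forward(x, training=False)[0]
    return np.ascontiguousarray(maps.transpose(2, 0, 1)[:, :h, :w])


# ---------------------------------------------------------------------------
# Training


def _validation_scores(
    model: UNet,
    val_pairs: Sequence[tuple[FrameImage, ReferenceAnnotation]],
    loss_eps: float = 1.0,
) -> tuple[float, dict[str, float], float]:
    """Validation loss and per-class Jaccard over all validation frames.

    Jaccard is computed per frame and averaged; frames where both reference
    and prediction are empty for a class are skipped for that class.
    """
    losses = []
    per_class: dict[str, list[float]] = {k: [] for k in CLASS_NAMES}
    for frame, ann in val_pairs:
        maps = predict_frame(model, frame)
        target = ann.stacked()
        losses.append(dice_loss(maps, target, eps=loss_eps))
        hard = maps >= 0.5
        for ci, name in enumerate(CLASS_NAMES):
            ref = target[ci] > 0.5
            if not ref.any() and not hard[ci].any():
                continue
            per_class[name].append(jaccard(hard[ci], ref))
    scores = {k: float(np.mean(v)) for k, v in per_class.items() if v}
    mean_j = float(np.mean(list(scores.values()))) if scores else 0.0
    return float(np.mean(losses)), scores, mean_j


def train(
    model: UNet,
    sampler: PatchSampler,
    val_pairs: Sequence[tuple[FrameImage, ReferenceAnnotation]],
    config: TrainConfig,
    augment: bool = True,
    loss_eps: float = 1.0,
) -> tuple[UNet, TrainHistory]:
    """Train with Adam + soft Dice loss and Jaccard-based early stopping.

    Every ``config.val_interval`` iterations the validation loss and
    per-class Jaccard are computed on all validation frames; training stops
    after ``config.patience`` validations without mean-Jaccard improvement
    (or at ``max_iterations``), and the model is restored to the state with
    the highest validation mean Jaccard before being returned.
    """
    if not val_pairs:
        raise ValueError("validation set is empty")
    if not any(sampler.stratum_sizes().values()):
        raise ValueError("training sampler has no frames")
    rng = np.random.default_rng([config.seed, 11])
    optimizer = Adam(model.params(), lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    history = TrainHistory()
    best_snapshot = None

    for it in range(1, config.max_iterations + 1):
        images, targets = sampler.batch(rng, augment_patch=augment)
        optimizer.zero_grad()
        probs = model.forward(images, training=True)
        loss, dprob = soft_dice_loss_and_grad(probs, targets, eps=loss_eps, channel_axis=-1)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}: loss={loss}")
        model.backward(dprob)
        optimizer.step()
        history.losses.append((it, loss))

        if it % config.val_interval == 0:
            val_loss, scores, mean_j = _validation_scores(model, val_pairs, loss_eps)
            history.validations.append(ValidationRecord(it, val_loss, scores, mean_j))
            improved = mean_j > stopper.best_score
            stop = stopper.update(mean_j, it)
            if improved:
                best_snapshot = model.snapshot()
                history.best_iteration = it
            if stop:
                break

    if best_snapshot is not None:
        model.restore(best_snapshot)
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints


def save_model(model: UNet, path: str | Path) -> Path:
    """Save weights as NPZ with a JSON sidecar holding the architecture config."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    snap = model.snapshot()
    arrays = {f"param_{i}": v for i, v in enumerate(snap["params"])}
    arrays.update({f"buffer_{i}": v for i, v in enumerate(snap["buffers"])})
    np.savez(p.with_suffix(".npz"), **arrays)
    sidecar = {"net_config": {k: v for k, v in vars(model.config).items()}}
    p.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return p.with_suffix(".npz")


def load_model(path: str | Path) -> UNet:
    p = Path(path)
    sidecar = json.loads(p.with_suffix(".json").read_text())
    model = UNet(NetConfig(**sidecar["net_config"]))
    data = np.load(p.with_suffix(".npz"))
    n_params = sum(1 for k in data.files if k.startswith("param_"))
    n_buffers = sum(1 for k in data.files if k.startswith("buffer_"))
    snap = {
        "params": [data[f"param_{i}"] for i in range(n_params)],
        "buffers": [data[f"buffer_{i}"] for i in range(n_buffers)],
    }
    model.restore(snap)
    return model
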