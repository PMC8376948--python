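"""The two U-Net segmenters: caries (U-CS) and structure (U-SS).

U-CS is a binary segmenter (background / caries) and U-SS a 7-class
anatomical segmenter.  Both share one architecture family — a five-level
U-Net with padded convolutions so the probability map covers the full input
frame — and one training loop: Adam on pixelwise cross-entropy, with an
optional false-positive penalty that charges lambda times the mean predicted
caries probability on images whose ground truth contains no caries at all.
The penalty is what lets caries-free radiographs participate in training a
detector that would otherwise only ever see positive supervision.

Epoch selection: after each epoch the mean per-pixel misclassification rate
on the validation set is recorded, and the returned model carries the
parameters of the epoch that minimized it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from . import nn
from .phantom import DatasetBundle, PhantomSample
from .types import CariesMask, Radiograph, StructureMask, ValidationError, MAX_INTENSITY

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "resize_to_input",
    "penalty_loss",
    "train",
    "train_curriculum",
    "predict",
    "save_model",
    "load_model",
    "desk_scale_configs",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of one segmenter.

    The reference configuration takes 572x572 inputs; ``desk_scale_configs``
    returns a 96x96 / width-8 profile that trains in minutes on one core.
    ``input_size`` must be divisible by ``2**(depth-1)`` so the pooling /
    up-convolution path closes.
    """

    n_classes: int = 2
    input_size: tuple[int, int] = (572, 572)
    depth: int = 5
    base_width: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be at least 2")
        if self.depth < 2:
            raise ValidationError("depth must be at least 2")
        f = 2 ** (self.depth - 1)
        h, w = self.input_size
        if h % f or w % f:
            raise ValidationError(
                f"input_size {self.input_size} must be divisible by {f} for depth {self.depth}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``learning_rate`` defaults to the reference value 1e-5 used at full
    scale; the desk profile overrides it (see ``desk_scale_configs``).
    ``fp_penalty`` is the lambda of the caries-free penalty term.
    """

    learning_rate: float = 1e-5
    max_epochs: int = 30
    fp_penalty: float = 1.0
    batch_size: int = 4
    rng_seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.fp_penalty < 0:
            raise ValidationError("fp_penalty (lambda) must be non-negative")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValidationError("max_epochs and batch_size must be positive")


def desk_scale_configs(n_classes: int = 2, seed: int = 0,
                       ) -> tuple[ModelConfig, TrainConfig]:
    """A small profile (96x96 input, base width 8, Adam 1e-3) for CPU runs."""
    return (ModelConfig(n_classes=n_classes, input_size=(96, 96), depth=5,
                        base_width=8, seed=seed),
            TrainConfig(learning_rate=1e-3, max_epochs=30, rng_seed=seed))


@dataclass
class TrainedModel:
    """A trained segmenter: config, parameters and the training log."""

    config: ModelConfig
    state: list[np.ndarray]
    optimal_epoch: int  # 1-based epoch whose parameters are stored
    log: list[dict] = field(default_factory=list)  # per-epoch train loss / val error

    def network(self) -> nn.UNet:
        net = _make_net(self.config)
        net.set_state(self.state)
        return net


def _make_net(config: ModelConfig) -> nn.UNet:
    return nn.UNet(n_classes=config.n_classes, depth=config.depth,
                   base_width=config.base_width, in_channels=1, seed=config.seed)


def build_model(config: ModelConfig) -> nn.UNet:
    """Instantiate an untrained network; deterministic in ``config.seed``."""
    config.validate()
    return _make_net(config)


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------


def _bilinear_resize(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    h, w = img.shape
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return img.astype(np.float32, copy=True)
    ry = np.linspace(0, h - 1, oh)
    rx = np.linspace(0, w - 1, ow)
    coords = np.stack(np.meshgrid(ry, rx, indexing="ij"))
    return ndi.map_coordinates(img.astype(np.float32), coords, order=1, mode="nearest")


def _nearest_resize(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    h, w = img.shape
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return img.copy()
    ry = np.rint(np.linspace(0, h - 1, oh)).astype(int)
    rx = np.rint(np.linspace(0, w - 1, ow)).astype(int)
    return img[np.ix_(ry, rx)]


def resize_to_input(radiograph: Radiograph, config: ModelConfig) -> np.ndarray:
    """Bilinear resize to the network grid and scale 12-bit counts to [0, 1]."""
    arr = _bilinear_resize(radiograph.pixels.astype(np.float32), config.input_size)
    return (arr / MAX_INTENSITY).astype(np.float32)


def _target_to_input(mask: np.ndarray, config: ModelConfig) -> np.ndarray:
    return _nearest_resize(np.asarray(mask), config.input_size).astype(np.int64)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def penalty_loss(prob: np.ndarray, target: CariesMask | np.ndarray,
                 fp_penalty: float = 1.0, caries_class: int = 1) -> float:
    """Cross-entropy plus the caries-free false-positive penalty.

    ``prob`` is a per-pixel class-probability array of shape ``(C, H, W)``;
    the penalty term is ``lambda * mean(prob[caries_class])`` when the target
    mask is empty and zero otherwise, so ``lambda = 0`` recovers plain
    cross-entropy.
    """
    target_arr = target.mask if isinstance(target, CariesMask) else np.asarray(target)
    prob = np.asarray(prob, dtype=np.float64)
    if prob.ndim != 3 or prob.shape[1:] != target_arr.shape:
        raise ValidationError("probability map and target shapes differ")
    eps = 1e-12
    c = prob.shape[0]
    onehot = np.arange(c)[:, None, None] == target_arr[None]
    # mean over pixels of the true-class negative log-likelihood
    ce = float(-(np.log(np.clip(prob, eps, None)) * onehot).sum(axis=0).mean())
    pen = 0.0
    if fp_penalty > 0 and not target_arr.any():
        pen = fp_penalty * float(prob[caries_class].mean())
    return ce + pen


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _prepare_arrays(samples: list[tuple[np.ndarray, np.ndarray]], config: ModelConfig,
                    ) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([s[0] for s in samples])[:, None]  # (n,1,h,w)
    ys = np.stack([s[1] for s in samples])
    return xs.astype(np.float32), ys.astype(np.int64)


def _as_xy(sample_pairs, config: ModelConfig):
    """(Radiograph, mask-array) pairs -> network-grid (x, y) pairs."""
    out = []
    for rad, mask in sample_pairs:
        out.append((resize_to_input(rad, config), _target_to_input(mask, config)))
    return out


def train(model: nn.UNet, train_set, validation_set, train_cfg: TrainConfig,
          config: ModelConfig, augment_fn=None, caries_class: int = 1,
          ) -> TrainedModel:
    """Optimize a segmenter and return the best-validation-epoch parameters.

    ``train_set`` / ``validation_set`` are lists of ``(Radiograph, target
    mask array)`` pairs; targets are integer class maps (binary for U-CS,
    structure labels for U-SS).  ``augment_fn(radiograph, mask, rng) ->
    (radiograph, mask)``, when given, is applied to training samples each
    epoch; validation samples are never augmented.
    """
    train_cfg.validate()
    if not train_set or not validation_set:
        raise ValidationError("train and validation sets must be non-empty")
    rng = np.random.default_rng(train_cfg.rng_seed)
    val_xy = _as_xy(validation_set, config)
    vx, vy = _prepare_arrays(val_xy, config)
    opt = nn.Adam(model, lr=train_cfg.learning_rate)

    log: list[dict] = []
    best_err = np.inf
    best_state = model.get_state()
    best_epoch = 0
    n = len(train_set)
    for epoch in range(1, train_cfg.max_epochs + 1):
        if augment_fn is not None:
            epoch_pairs = [augment_fn(rad, mask, rng) for rad, mask in train_set]
        else:
            epoch_pairs = train_set
        xy = _as_xy(epoch_pairs, config)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            bx, by = _prepare_arrays([xy[i] for i in idx], config)
            logits = model.forward(bx)
            loss, dlog = nn.softmax_ce_loss(
                logits, by, fp_penalty=train_cfg.fp_penalty, caries_class=caries_class)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            model.backward(dlog)
            opt.step()
            total += loss * len(idx)
        val_err = _error_rate(model, vx, vy, train_cfg.batch_size)
        log.append({"epoch": epoch, "train_loss": total / n, "val_error": val_err})
        if val_err < best_err:
            best_err = val_err
            best_state = model.get_state()
            best_epoch = epoch
    model.set_state(best_state)
    return TrainedModel(config=config, state=best_state, optimal_epoch=best_epoch, log=log)


def _error_rate(model: nn.UNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    """Mean per-pixel misclassification rate."""
    wrong = 0
    total = 0
    for start in range(0, len(x), batch):
        logits = model.forward(x[start:start + batch])
        pred = logits.argmax(axis=1)
        wrong += int((pred != y[start:start + batch]).sum())
        total += pred.size
    return wrong / total


# ---------------------------------------------------------------------------
# curriculum
# ---------------------------------------------------------------------------


def train_curriculum(model_cfg: ModelConfig, bundle: DatasetBundle,
                     train_cfg: TrainConfig, val_fraction: float = 0.2,
                     evaluate_fn=None, augment_fn=None) -> list[dict]:
    """Train U-CS by accumulating the subsets d_a, then +d_b, then +d_c.

    Returns one record per stage with the stage name, cumulative training
    size, the :class:`TrainedModel`, and — when ``evaluate_fn(trained,
    stage_samples)`` is supplied — its evaluation output for the stage's
    held-out samples (``bundle.d_d``).
    """
    stages = [("d_a", list(bundle.d_a)),
              ("d_a+d_b", list(bundle.d_a) + list(bundle.d_b)),
              ("d_a+d_b+d_c", list(bundle.d_a) + list(bundle.d_b) + list(bundle.d_c))]
    records = []
    for i, (name, samples) in enumerate(stages):
        rng = np.random.default_rng(train_cfg.rng_seed + i)
        order = rng.permutation(len(samples))
        n_val = max(1, int(round(val_fraction * len(samples))))
        val_idx = set(order[:n_val].tolist())
        pairs = [(s.radiograph, s.caries.mask) for s in samples]
        train_pairs = [p for j, p in enumerate(pairs) if j not in val_idx]
        val_pairs = [p for j, p in enumerate(pairs) if j in val_idx]
        model = build_model(model_cfg)
        trained = train(model, train_pairs, val_pairs, train_cfg, model_cfg,
                        augment_fn=augment_fn)
        rec = {"stage": name, "n_train": len(train_pairs), "model": trained}
        if evaluate_fn is not None:
            rec["evaluation"] = evaluate_fn(trained, bundle.d_d)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict(model: TrainedModel | nn.UNet, radiograph: Radiograph,
            config: ModelConfig | None = None) -> np.ndarray:
    """Class-probability map at the radiograph's native resolution.

    The radiograph is resized to the network grid, passed through the net,
    and each probability channel is bilinearly resized back and renormalized
    so pixels stay on the simplex.  Shape ``(n_classes, H, W)``.
    """
    if isinstance(model, TrainedModel):
        config = model.config
        net = model.network()
    else:
        if config is None:
            raise ValidationError("config required when passing a bare network")
        net = model
    x = resize_to_input(radiograph, config)[None, None]
    logits = net.forward(x)
    prob = nn.softmax(logits)[0]  # (C, h, w)
    out_hw = radiograph.shape
    chans = [_bilinear_resize(prob[c].astype(np.float32), out_hw) for c in range(prob.shape[0])]
    full = np.stack(chans).astype(np.float64)
    full = np.clip(full, 0.0, None)
    full /= full.sum(axis=0, keepdims=True)
    return full.astype(np.float32)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str) -> None:
    """Single-file .npz checkpoint holding config, parameters and log."""
    meta = {"config": asdict(model.config), "optimal_epoch": model.optimal_epoch,
            "log": model.log}
    arrays = {f"p{i}": a for i, a in enumerate(model.state)}
    np.savez(path, meta=json.dumps(meta), n_arrays=len(model.state), **arrays)


def load_model(path: str) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        n = int(z["n_arrays"])
        state = [z[f"p{i}"] for i in range(n)]
    cfg_d = meta["config"]
    cfg_d["input_size"] = tuple(cfg_d["input_size"])
    config = ModelConfig(**cfg_d)
    return TrainedModel(config=config, state=state,
                        optimal_epoch=meta["optimal_epoch"], log=meta["log"])
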