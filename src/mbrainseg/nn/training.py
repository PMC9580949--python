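"""Training protocol: class-weighted soft Dice loss, Adam, plateau LR decay.

The loss for per-voxel class probabilities p and one-hot target t is

    L = 1 - sum_c w_c * (2 * sum(p_c t_c) + eps) / (sum(p_c) + sum(t_c) + eps)

with eps = 1e-5 and weights w normalized to sum to one.  By default weights
are inverse class-voxel frequencies computed on the training set, which
counters the extreme background/foreground imbalance of head MRI.

Optimization follows the whole-image, batch-size-1 protocol: Adam, learning
rate multiplied by ``lr_factor`` when validation loss fails to improve for
``lr_patience`` epochs, early stopping after ``early_stopping_patience``
stagnant epochs, best-validation weights retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..volumes import LabelMask, Volume, read_nifti
from . import autodiff as ad
from .autodiff import Tensor
from .unet import NetworkConfig, ResidualUNet3D, build_model

__all__ = [
    "TrainConfig",
    "weighted_dice_loss",
    "inverse_frequency_weights",
    "train",
    "predict_mask",
    "grid_search",
    "save_model",
    "load_model",
    "load_dataset",
]

EPS = 1e-5


@dataclass
class TrainConfig:
    initial_lr: float = 5e-5
    lr_factor: float = 0.7
    lr_patience: int = 15
    max_epochs: int = 500
    early_stopping_patience: int | None = None  # default: 3 * lr_patience
    batch_size: int = 1
    val_fraction: float = 0.2
    class_weights: tuple[float, ...] | None = None  # None -> inverse frequency
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.batch_size != 1:
            raise ValueError("whole-image training uses batch size 1")
        if self.early_stopping_patience is None:
            self.early_stopping_patience = 3 * self.lr_patience


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    oh = np.zeros((n_classes,) + target.shape, dtype=np.float32)
    for c in range(n_classes):
        oh[c] = target == c
    return oh


def _normalize_weights(weights, n_classes: int) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (n_classes,):
        raise ValueError(f"expected {n_classes} class weights, got shape {w.shape}")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("class weights must be non-negative with positive sum")
    return (w / w.sum()).astype(np.float32)


def inverse_frequency_weights(targets: list[np.ndarray], n_classes: int) -> np.ndarray:
    """Inverse class-voxel-frequency weights over a training set, normalized."""
    counts = np.zeros(n_classes, dtype=np.float64)
    for t in targets:
        counts += np.bincount(np.asarray(t).ravel().astype(np.int64), minlength=n_classes)[:n_classes]
    counts = np.maximum(counts, 1.0)
    return _normalize_weights(1.0 / counts, n_classes)


def weighted_dice_loss(probs, target, weights=None) -> Tensor | float:
    """Class-weighted soft Dice loss in [0, 1].

    ``probs``: Tensor or array (n_classes, X, Y, Z) of per-voxel
    probabilities; ``target``: integer label array (or LabelMask) of the
    spatial shape.  Returns a scalar Tensor when ``probs`` is part of a
    graph, else a float.
    """
    if isinstance(target, LabelMask):
        target = target.data
    target = np.asarray(target)
    is_tensor = isinstance(probs, Tensor)
    p = probs if is_tensor else ad.constant(np.asarray(probs, dtype=np.float32))
    n_classes = p.data.shape[0]
    if p.data.shape[1:] != target.shape:
        raise ValueError(f"shape mismatch: probs {p.data.shape[1:]} vs target {target.shape}")
    if weights is None:
        weights = np.ones(n_classes)
    w = _normalize_weights(weights, n_classes)
    onehot = _one_hot(target, n_classes)
    loss = ad.constant(np.float32(1.0))
    for c in range(n_classes):
        pc = Tensor(p.data[c], parents=(p,), backward=_channel_backward(p, c)) if is_tensor else ad.constant(p.data[c])
        tc = ad.constant(onehot[c])
        inter = tsum_scalar(ad.mul(pc, tc))
        denom = ad.add(tsum_scalar(pc), ad.constant(np.float32(onehot[c].sum())))
        dice_c = ad.div(
            ad.add(ad.mul(ad.constant(np.float32(2.0)), inter), ad.constant(np.float32(EPS))),
            ad.add(denom, ad.constant(np.float32(EPS))),
        )
        loss = ad.sub(loss, ad.mul(ad.constant(np.float32(w[c])), dice_c))
    return loss if is_tensor else float(loss.data)


def tsum_scalar(t: Tensor) -> Tensor:
    return ad.tsum(t, axis=None)


def _channel_backward(p: Tensor, c: int):
    def backward(g):
        full = np.zeros_like(p.data)
        full[c] = g
        p._accumulate(full)

    return backward


class Adam:
    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def load_dataset(data_dir) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load staged (image, mask) pairs as arrays from a directory."""
    data_dir = Path(data_dir)
    pairs = []
    for img_path in sorted(data_dir.glob("img_*.nii*")):
        msk_path = img_path.with_name(img_path.name.replace("img_", "msk_"))
        if not msk_path.exists():
            continue
        img = read_nifti(img_path)
        msk = read_nifti(msk_path, as_mask=True)
        pairs.append((img.data.astype(np.float32), msk.data.astype(np.int64)))
    if not pairs:
        raise ValueError(f"no image/mask pairs found in {data_dir}")
    return pairs


def _split(n: int, val_fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 1 else 0
    return order[n_val:], order[:n_val]


def train(
    model: ResidualUNet3D,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    tcfg: TrainConfig,
    target_label: int | None = None,
    verbose: bool = False,
) -> tuple[ResidualUNet3D, pd.DataFrame]:
    """Train in place; returns the model (best-validation weights) and history.

    ``target_label`` collapses a multi-label mask to {0,1} on that label
    (e.g. direct small-region segmentation); None binarizes any-foreground
    for 2-class models and keeps labels as-is otherwise.
    """
    if not dataset:
        raise ValueError("empty dataset")
    n_classes = model.cfg.n_classes
    prepared = []
    for img, msk in dataset:
        if target_label is not None:
            t = (msk == target_label).astype(np.int64)
        elif n_classes == 2:
            t = (msk > 0).astype(np.int64)
        else:
            t = msk.astype(np.int64)
        if t.max() >= n_classes:
            raise ValueError(f"label {t.max()} exceeds n_classes={n_classes}")
        prepared.append((img.astype(np.float32), t))

    rng = np.random.default_rng(tcfg.seed)
    model.reseed_dropout(tcfg.seed + 1)
    train_idx, val_idx = _split(len(prepared), tcfg.val_fraction, rng)
    if len(prepared) == 1:
        train_idx = np.array([0])
        val_idx = np.array([0])
    weights = (
        _normalize_weights(tcfg.class_weights, n_classes)
        if tcfg.class_weights is not None
        else inverse_frequency_weights([prepared[i][1] for i in train_idx], n_classes)
    )

    opt = Adam(model.parameters(), tcfg.initial_lr)
    best_val = np.inf
    best_state = model.state_dict()
    lr_wait = stop_wait = 0
    rows = []
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(train_idx)
        train_losses = []
        for i in order:
            img, t = prepared[i]
            probs = model.forward(img, training=True)
            loss = weighted_dice_loss(probs, t, weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        val_losses = []
        with ad.no_grad():
            for i in val_idx:
                img, t = prepared[i]
                probs = model.forward(img, training=False)
                val_losses.append(float(weighted_dice_loss(probs, t, weights).data))
        train_loss = float(np.mean(train_losses))
        val_loss = float(np.mean(val_losses)) if val_losses else train_loss
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": opt.lr})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}  lr {opt.lr:.2e}")
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = model.state_dict()
            lr_wait = stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if lr_wait >= tcfg.lr_patience:
                opt.lr *= tcfg.lr_factor
                lr_wait = 0
            if stop_wait >= tcfg.early_stopping_patience:
                break
    model.load_state_dict(best_state)
    return model, pd.DataFrame(rows)


def predict_mask(
    model: ResidualUNet3D,
    vol: Volume | np.ndarray,
    threshold: float = 0.5,
    labels: dict[int, str] | None = None,
) -> LabelMask:
    """Whole-volume single forward pass; argmax over classes (binary models:
    foreground probability >= threshold)."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    probs = model.predict_probs(data.astype(np.float32))
    if model.cfg.n_classes == 2:
        pred = (probs[1] >= threshold).astype(np.int32)
    else:
        pred = np.argmax(probs, axis=0).astype(np.int32)
    spacing = vol.spacing if isinstance(vol, Volume) else (1.0, 1.0, 1.0)
    origin = vol.origin if isinstance(vol, Volume) else (0.0, 0.0, 0.0)
    return LabelMask(pred, spacing, origin, labels=dict(labels or {}))


def grid_search(
    configs: list[tuple[NetworkConfig, TrainConfig]],
    dataset: list[tuple[np.ndarray, np.ndarray]],
    budget_epochs: int,
    out_csv=None,
) -> pd.DataFrame:
    """Train every configuration under identical splits for ``budget_epochs``
    and rank by best validation loss."""
    if not configs:
        raise ValueError("at least one configuration required")
    rows = []
    for idx, (ncfg, tcfg) in enumerate(configs):
        tcfg = TrainConfig(
            initial_lr=tcfg.initial_lr,
            lr_factor=tcfg.lr_factor,
            lr_patience=tcfg.lr_patience,
            max_epochs=budget_epochs,
            early_stopping_patience=tcfg.early_stopping_patience,
            val_fraction=tcfg.val_fraction,
            class_weights=tcfg.class_weights,
            seed=tcfg.seed,
        )
        model = build_model(ncfg)
        _, history = train(model, dataset, tcfg)
        rows.append(
            {
                "config": idx,
                "depth": ncfg.depth,
                "base_filters": ncfg.base_filters,
                "dropout_rate": ncfg.dropout_rate,
                "initial_lr": tcfg.initial_lr,
                "best_val_loss": float(history["val_loss"].min()),
                "epochs_run": len(history),
            }
        )
    table = pd.DataFrame(rows).sort_values("best_val_loss").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if out_csv:
        table.to_csv(out_csv, index=False)
    return table


def save_model(model: ResidualUNet3D, out_dir, history: pd.DataFrame | None = None) -> None:
    """Persist weights (npz), config snapshot (json) and history (csv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "weights.npz", **model.state_dict())
    cfg = model.cfg
    (out_dir / "config.json").write_text(
        json.dumps(
            {
                "depth": cfg.depth,
                "base_filters": cfg.base_filters,
                "dropout_rate": cfg.dropout_rate,
                "in_channels": cfg.in_channels,
                "n_classes": cfg.n_classes,
                "seed": cfg.seed,
            },
            indent=2,
        )
    )
    if history is not None:
        history.to_csv(out_dir / "history.csv", index=False)


def load_model(model_dir) -> ResidualUNet3D:
    model_dir = Path(model_dir)
    cfg = NetworkConfig(**json.loads((model_dir / "config.json").read_text()))
    model = build_model(cfg)
    with np.load(model_dir / "weights.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model
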