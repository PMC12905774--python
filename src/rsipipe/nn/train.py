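"""Training loop for the 3D dense classifiers.

Binary cross-entropy over the two-way softmax output, AdamW (decoupled weight
decay), linear warm-up followed by cosine annealing of the learning rate, a
stratified internal validation split used only for best-epoch selection, and
deterministic behaviour under a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ..errors import ConfigurationError
from ..metrics import roc_auc
from ..prep import AugmentPolicy, augment, ModelInputTensor
from . import autograd as ag
from .autograd import Tensor
from .densenet import DenseNet3d, DenseNetConfig

__all__ = ["TrainConfig", "TrainedClassifier", "AdamW", "lr_at_step",
           "train_classifier", "predict_proba", "save_classifier", "load_classifier"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    total_epochs: int = 20
    batch_size: int = 8
    warmup_steps: int | None = None  # default: 10% of total steps
    internal_val_fraction: float = 0.10
    seed: int = 0
    best_epoch_metric: str = "val_auc"  # or "val_loss"
    standardize_scalar: bool = True

    def validate(self) -> None:
        if not 0 < self.internal_val_fraction < 1:
            raise ConfigurationError("internal_val_fraction must be in (0, 1)")
        if self.best_epoch_metric not in ("val_auc", "val_loss"):
            raise ConfigurationError("best_epoch_metric must be val_auc or val_loss")
        if self.total_epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("total_epochs and batch_size must be >= 1")


def lr_at_step(step: int, total_steps: int, warmup_steps: int, base_lr: float) -> float:
    """Linear ramp 0 -> base_lr over the warm-up, then cosine decay to 0."""
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * step / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    t = min(step - warmup_steps, span) / span
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * t))


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * self.weight_decay * p.data
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedClassifier:
    model: DenseNet3d
    net_config: DenseNetConfig
    train_config: TrainConfig
    best_epoch: int
    history: pd.DataFrame
    scalar_mean: float = 0.0
    scalar_std: float = 1.0

    def standardize(self, scalars: np.ndarray | None) -> np.ndarray | None:
        if scalars is None:
            return None
        return (np.asarray(scalars, dtype=float) - self.scalar_mean) / self.scalar_std


def _forward_logits(model: DenseNet3d, x: np.ndarray, scalars: np.ndarray | None) -> Tensor:
    if model.config.scalar_fusion:
        return model(Tensor(x), scalar=scalars)
    return model(Tensor(x))


def train_classifier(
    volumes: np.ndarray,
    scalars: np.ndarray | None,
    labels: np.ndarray,
    net_config: DenseNetConfig,
    train_config: TrainConfig,
    augment_policy: AugmentPolicy | None = None,
    val_indices: np.ndarray | None = None,
) -> TrainedClassifier:
    """Train one classifier on (N, C, x, y, z) volumes with binary labels.

    A stratified ``internal_val_fraction`` of the data (matched by label) is
    withheld strictly for best-epoch selection; the parameters of the epoch
    with the best validation metric are restored before returning. An
    explicit ``val_indices`` array overrides the internal split (used when an
    outer protocol has already carved out the validation patients).
    """
    train_config.validate()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("training set must contain both classes (stratification impossible)")
    if net_config.scalar_fusion and scalars is None:
        raise ConfigurationError("scalar-fusion model requires per-patient scalars")

    idx = np.arange(len(labels))
    if val_indices is not None:
        val_idx = np.asarray(val_indices, dtype=int)
        tr_idx = np.setdiff1d(idx, val_idx)
        if len(np.unique(labels[tr_idx])) < 2 or len(np.unique(labels[val_idx])) < 2:
            raise ConfigurationError("explicit validation split must leave both classes on each side")
    else:
        tr_idx, val_idx = train_test_split(
            idx,
            test_size=train_config.internal_val_fraction,
            stratify=labels,
            random_state=train_config.seed % (2**32),
        )

    scalar_mean, scalar_std = 0.0, 1.0
    s_all = None
    if scalars is not None:
        s_all = np.asarray(scalars, dtype=float)
        if train_config.standardize_scalar:
            scalar_mean = float(s_all[tr_idx].mean())
            scalar_std = float(max(s_all[tr_idx].std(), 1e-12))
        s_all = (s_all - scalar_mean) / scalar_std

    model = DenseNet3d(net_config, seed=train_config.seed)
    opt = AdamW(model.parameters(), lr=train_config.learning_rate,
                weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)

    n_train = len(tr_idx)
    steps_per_epoch = int(np.ceil(n_train / train_config.batch_size))
    total_steps = steps_per_epoch * train_config.total_epochs
    warmup = (train_config.warmup_steps if train_config.warmup_steps is not None
              else max(1, int(0.1 * total_steps)))

    best_metric = -np.inf
    best_state = model.state_dict()
    best_epoch = 1
    history_rows = []
    step = 0
    for epoch in range(1, train_config.total_epochs + 1):
        model.train()
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, n_train, train_config.batch_size):
            batch = order[start:start + train_config.batch_size]
            xb = volumes[batch].astype(np.float64)
            if augment_policy is not None:
                xb = np.stack([
                    augment(ModelInputTensor(channels=("c",) * xb.shape[1], array=xb[i].astype(np.float32)),
                            rng, augment_policy).array
                    for i in range(len(batch))
                ]).astype(np.float64)
            sb = s_all[batch] if (s_all is not None and net_config.scalar_fusion) else None
            logits = _forward_logits(model, xb, sb)
            loss = ag.softmax_cross_entropy(logits, labels[batch])
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr_at_step(step, total_steps, warmup, train_config.learning_rate))
            losses.append(float(loss.data))
            step += 1

        model.eval()
        val_s = s_all[val_idx] if (s_all is not None and net_config.scalar_fusion) else None
        val_logits = _forward_logits(model, volumes[val_idx].astype(np.float64), val_s)
        val_p = ag.softmax(val_logits.data)[:, 1]
        val_loss = float(-np.mean(np.log(np.clip(
            np.where(labels[val_idx] == 1, val_p, 1 - val_p), 1e-15, None))))
        val_auc = roc_auc(val_p, labels[val_idx])
        metric = val_auc if train_config.best_epoch_metric == "val_auc" else -val_loss
        history_rows.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_auc": val_auc,
            "lr": lr_at_step(step - 1, total_steps, warmup, train_config.learning_rate),
        })
        if metric > best_metric:
            best_metric = metric
            best_state = model.state_dict()
            best_epoch = epoch

    model.load_state_dict(best_state)
    model.eval()
    return TrainedClassifier(
        model=model,
        net_config=net_config,
        train_config=train_config,
        best_epoch=best_epoch,
        history=pd.DataFrame(history_rows),
        scalar_mean=scalar_mean,
        scalar_std=scalar_std,
    )


def predict_proba(
    trained: TrainedClassifier,
    volumes: np.ndarray,
    scalars: np.ndarray | None = None,
    batch_size: int = 16,
) -> np.ndarray:
    """Positive-class (csPCa) softmax probability per patient, order preserved."""
    model = trained.model
    model.eval()
    s = trained.standardize(scalars) if model.config.scalar_fusion else None
    if model.config.scalar_fusion and s is None:
        raise ConfigurationError("scalar-fusion model requires per-patient scalars")
    out = []
    for start in range(0, len(volumes), batch_size):
        xb = np.asarray(volumes[start:start + batch_size], dtype=np.float64)
        sb = s[start:start + batch_size] if s is not None else None
        logits = _forward_logits(model, xb, sb)
        out.append(ag.softmax(logits.data)[:, 1])
    return np.concatenate(out)


def save_classifier(trained: TrainedClassifier, path) -> Path:
    """Self-describing checkpoint: parameters + buffers + config snapshot (npz)."""
    path = Path(path)
    meta = {
        "net_config": asdict(trained.net_config),
        "train_config": asdict(trained.train_config),
        "best_epoch": trained.best_epoch,
        "scalar_mean": trained.scalar_mean,
        "scalar_std": trained.scalar_std,
        "history": trained.history.to_dict(orient="list"),
    }
    arrays = {f"state::{k}": v for k, v in trained.model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_classifier(path) -> TrainedClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state::"):]: data[k] for k in data.files if k.startswith("state::")}
    nc = meta["net_config"]
    nc["block_layers"] = tuple(nc["block_layers"])
    net_config = DenseNetConfig(**nc)
    train_config = TrainConfig(**meta["train_config"])
    model = DenseNet3d(net_config, seed=train_config.seed)
    model.load_state_dict(state)
    model.eval()
    return TrainedClassifier(
        model=model,
        net_config=net_config,
        train_config=train_config,
        best_epoch=meta["best_epoch"],
        history=pd.DataFrame(meta["history"]),
        scalar_mean=meta["scalar_mean"],
        scalar_std=meta["scalar_std"],
    )
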