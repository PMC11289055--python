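"""Preprocessing, losses, optimizers and the seeded training loop.

Training minimises the absolute-error loss between the predicted global
score ``p = p_l + p_r`` and the annotated global score

    L = sum_i | p_i - p_hat_i |        (batch sum form)

with stochastic gradient descent. The sum form above is what the loss
definition states per batch; optimisation defaults to the batch *mean*
so the learning rate is stable across batch sizes — both reductions are
available and the choice is logged with every run. MSE, smooth-L1 and
Huber losses, and Adadelta/Adam/AdamW/RMSprop optimizers, are provided
as interchangeable options for ablation.

When online score-correlated CutMix is enabled, every image in a batch
is mixed once per epoch with a uniformly drawn partner from the same
batch, and its target becomes the provenance-weighted score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .augment import mix_scores, sample_cutmix_box
from .model import ViTNetwork

__all__ = [
    "TrainConfig",
    "preprocess",
    "compute_loss",
    "l1_loss",
    "make_optimizer",
    "train",
    "LOSSES",
    "OPTIMIZERS",
]

_VAR_FLOOR = 1e-6


def preprocess(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Resize to ``(size, size, 3)`` and standardise per image.

    Grayscale inputs are replicated across three channels. Intensities
    are shifted to zero mean and scaled to unit variance; a variance
    floor maps constant images to all zeros. Applying the function to
    an already-preprocessed image is a no-op up to float tolerance.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if img.ndim != 3 or img.shape[2] not in (1, 3):
        raise ValueError("expected a single- or 3-channel image")
    if img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    if img.shape[0] != size or img.shape[1] != size:
        img = resize(img, (size, size), order=1, anti_aliasing=True, mode="reflect")
    mu = img.mean()
    sd = img.std()
    img = (img - mu) / max(sd, _VAR_FLOOR)
    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# losses: each returns (value, dvalue/dpred) for the requested reduction


def _l1(r: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    return np.abs(r), np.sign(r)


def _mse(r: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    return r * r, 2.0 * r


def _smooth_l1(r: np.ndarray, beta: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    small = np.abs(r) < beta
    val = np.where(small, 0.5 * r * r / beta, np.abs(r) - 0.5 * beta)
    grad = np.where(small, r / beta, np.sign(r))
    return val, grad


def _huber(r: np.ndarray, delta: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    small = np.abs(r) <= delta
    val = np.where(small, 0.5 * r * r, delta * (np.abs(r) - 0.5 * delta))
    grad = np.where(small, r, delta * np.sign(r))
    return val, grad


LOSSES: Dict[str, Callable] = {
    "l1": _l1,
    "mse": _mse,
    "smooth_l1": _smooth_l1,
    "huber": _huber,
}


def compute_loss(
    predictions: np.ndarray,
    targets: np.ndarray,
    loss: str = "l1",
    reduction: str = "mean",
) -> Tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the predictions."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must have equal shapes")
    try:
        fn = LOSSES[loss]
    except KeyError:
        raise ValueError(f"unknown loss {loss!r}; options: {sorted(LOSSES)}") from None
    val, grad = fn(predictions - targets)
    if reduction == "mean":
        return float(val.mean()), grad / val.size
    if reduction == "sum":
        return float(val.sum()), grad
    raise ValueError("reduction must be 'mean' or 'sum'")


def l1_loss(
    predictions: np.ndarray, targets: np.ndarray, reduction: str = "sum"
) -> float:
    """Absolute-error loss; the ``sum`` reduction is the per-batch form."""
    return compute_loss(predictions, targets, loss="l1", reduction=reduction)[0]


# ---------------------------------------------------------------------------
# optimizers


class _Optimizer:
    def __init__(self, params: Dict[str, np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr

    def step(self, grads: Dict[str, np.ndarray]) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, params, lr, momentum: float = 0.9, weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads):
        for k, p in self.params.items():
            g = grads[k] + self.weight_decay * p
            self.buf[k] = self.momentum * self.buf[k] + g
            p -= self.lr * self.buf[k]


class Adam(_Optimizer):
    decoupled = False

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads):
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            if self.weight_decay and self.decoupled:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    decoupled = True

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2):
        super().__init__(params, lr, betas=betas, eps=eps, weight_decay=weight_decay)


class RMSprop(_Optimizer):
    def __init__(self, params, lr, alpha=0.99, eps=1e-8):
        super().__init__(params, lr)
        self.alpha = alpha
        self.eps = eps
        self.sq = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads):
        for k, p in self.params.items():
            g = grads[k]
            self.sq[k] = self.alpha * self.sq[k] + (1 - self.alpha) * g * g
            p -= self.lr * g / (np.sqrt(self.sq[k]) + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, params, lr=1.0, rho=0.9, eps=1e-6):
        super().__init__(params, lr)
        self.rho = rho
        self.eps = eps
        self.sq = {k: np.zeros_like(v) for k, v in params.items()}
        self.dx = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads):
        for k, p in self.params.items():
            g = grads[k]
            self.sq[k] = self.rho * self.sq[k] + (1 - self.rho) * g * g
            upd = np.sqrt((self.dx[k] + self.eps) / (self.sq[k] + self.eps)) * g
            self.dx[k] = self.rho * self.dx[k] + (1 - self.rho) * upd * upd
            p -= self.lr * upd


OPTIMIZERS = {
    "sgd": SGD,
    "adam": Adam,
    "adamw": AdamW,
    "rmsprop": RMSprop,
    "adadelta": Adadelta,
}


def make_optimizer(name: str, params: Dict[str, np.ndarray], config: "TrainConfig"):
    try:
        cls = OPTIMIZERS[name]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; options: {sorted(OPTIMIZERS)}"
        ) from None
    if cls is SGD:
        return SGD(
            params,
            config.learning_rate,
            momentum=config.momentum,
            weight_decay=config.weight_decay,
        )
    return cls(params, config.learning_rate)


# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (benchmark defaults: batch 32,
    learning rate 1e-3, 60 epochs, L1 loss, SGD with momentum 0.9)."""

    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 60
    loss: str = "l1"
    reduction: str = "mean"
    optimizer: str = "sgd"
    momentum: float = 0.9
    weight_decay: float = 0.0
    cutmix_enabled: bool = True
    cutmix_area_range: Tuple[float, float] = (0.05, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.cutmix_enabled and self.batch_size < 2:
            raise ValueError("online CutMix needs an in-batch partner (batch >= 2)")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _cutmix_batch(
    xb: np.ndarray,
    yb: np.ndarray,
    rng: np.random.Generator,
    area_range: Tuple[float, float],
) -> Tuple[np.ndarray, np.ndarray]:
    """Mix every batch element once with a random in-batch partner."""
    nb, h, w = xb.shape[0], xb.shape[1], xb.shape[2]
    xm = xb.copy()
    ym = yb.astype(np.float64).copy()
    for i in range(nb):
        j = int(rng.integers(0, nb - 1))
        if j >= i:
            j += 1
        spec = sample_cutmix_box(h, w, area_range, rng)
        r0, c0, r1, c1 = spec.box
        xm[i, r0:r1, c0:c1] = xb[j, r0:r1, c0:c1]
        ym[i] = mix_scores(spec.lam, yb[i], yb[j])
    return xm, ym


def train(
    network: ViTNetwork,
    images: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    val_images: Optional[np.ndarray] = None,
    val_targets: Optional[np.ndarray] = None,
    callback: Optional[Callable[[int, float], None]] = None,
) -> List[Dict[str, float]]:
    """Seeded in-place optimisation of ``network`` on preprocessed images.

    ``images`` is ``(n, S, S, 3)`` float, ``targets`` the global scores
    ``(n,)`` (or per-lung pairs ``(n, 2)``, in which case each head
    output is supervised directly and CutMix must be off). Returns the
    per-epoch history ``[{"epoch", "train_loss", "val_mae"?}, ...]``.
    All randomness (shuffling, CutMix partners and boxes) derives from
    ``config.seed``, so identical calls produce identical traces.
    """
    images = np.asarray(images, dtype=np.float32)
    targets = np.asarray(targets, dtype=np.float64)
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    per_lung = targets.ndim == 2
    if per_lung and config.cutmix_enabled:
        raise ValueError("per-lung supervision is incompatible with CutMix targets")
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(config.optimizer, network.params, config)
    history: List[Dict[str, float]] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, nb_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = images[idx], targets[idx]
            if config.cutmix_enabled and len(idx) >= 2:
                xb, yb = _cutmix_batch(xb, yb, rng, config.cutmix_area_range)
            out, cache = network.forward(xb, return_cache=True)
            if per_lung:
                loss, dpred = compute_loss(out, yb, config.loss, config.reduction)
                dout = dpred
            else:
                p = out.sum(axis=1)
                loss, dpred = compute_loss(p, yb, config.loss, config.reduction)
                dout = np.repeat(dpred[:, None], 2, axis=1)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}"
                )
            grads = network.backward(dout.astype(network.dtype), cache)
            opt.step(grads)
            epoch_loss += loss
            nb_batches += 1
        entry: Dict[str, float] = {
            "epoch": float(epoch),
            "train_loss": epoch_loss / nb_batches,
        }
        if val_images is not None and val_targets is not None:
            pv = network.predict_global(val_images)
            entry["val_mae"] = float(np.mean(np.abs(pv - np.asarray(val_targets))))
        history.append(entry)
        if callback is not None:
            callback(epoch, entry["train_loss"])
    return history
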