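"""Scikit-learn style estimator wrapping the transformer regressor.

``ViTRegressor`` follows the sklearn contract — hyperparameters in
``__init__``, state learned by :meth:`fit` stored in trailing-underscore
attributes, ``get_params``/``set_params`` inherited — so it composes
with sklearn model selection. ``X`` is a stack of raw images
``(n, H, W)`` or ``(n, H, W, C)``; ``y`` holds global severity scores
``(n,)`` or per-lung pairs ``(n, 2)``.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import ViTConfig, ViTNetwork
from .training import TrainConfig, preprocess, train

__all__ = ["ViTRegressor"]


class ViTRegressor(RegressorMixin, BaseEstimator):
    """Per-lung severity regressor over chest images.

    Defaults are the benchmark configuration: tiny ViT backbone
    (224x224x3 input, patch 16, depth 12, width 192) with a 128->2
    regression head, trained 60 epochs with batch 32, learning rate
    1e-3, L1 loss, SGD momentum 0.9 and online score-correlated CutMix.
    For desk-scale work pass the nano geometry (``image_size=64,
    patch_size=8, depth=4, embed_dim=64, num_heads=2``).

    Attributes set by :meth:`fit`: ``network_`` (the parameterised
    model), ``loss_trace_`` (per-epoch history), ``train_mean_`` (mean
    training target, the predict-the-mean reference).
    """

    def __init__(
        self,
        image_size: int = 224,
        channels: int = 3,
        patch_size: int = 16,
        depth: int = 12,
        embed_dim: int = 192,
        num_heads: int = 3,
        mlp_ratio: float = 4.0,
        head_hidden: int = 128,
        head_activation: str = "none",
        per_lung_max: float = 4.0,
        clamp_output: bool = True,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        epochs: int = 60,
        loss: str = "l1",
        reduction: str = "mean",
        optimizer: str = "sgd",
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        cutmix: bool = True,
        cutmix_area_range: Tuple[float, float] = (0.05, 0.4),
        random_state: int = 0,
    ) -> None:
        self.image_size = image_size
        self.channels = channels
        self.patch_size = patch_size
        self.depth = depth
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.mlp_ratio = mlp_ratio
        self.head_hidden = head_hidden
        self.head_activation = head_activation
        self.per_lung_max = per_lung_max
        self.clamp_output = clamp_output
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.loss = loss
        self.reduction = reduction
        self.optimizer = optimizer
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.cutmix = cutmix
        self.cutmix_area_range = cutmix_area_range
        self.random_state = random_state

    # ------------------------------------------------------------------
    def vit_config(self) -> ViTConfig:
        return ViTConfig(
            image_size=self.image_size,
            channels=self.channels,
            patch_size=self.patch_size,
            depth=self.depth,
            embed_dim=self.embed_dim,
            num_heads=self.num_heads,
            mlp_ratio=self.mlp_ratio,
            head_hidden=self.head_hidden,
            head_activation=self.head_activation,
            per_lung_max=self.per_lung_max,
            clamp_output=self.clamp_output,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            loss=self.loss,
            reduction=self.reduction,
            optimizer=self.optimizer,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            cutmix_enabled=self.cutmix,
            cutmix_area_range=self.cutmix_area_range,
            seed=self.random_state,
        )

    def _preprocess(self, X: Sequence[np.ndarray]) -> np.ndarray:
        return np.stack([preprocess(img, size=self.image_size) for img in X])

    # ------------------------------------------------------------------
    def fit(
        self,
        X: Sequence[np.ndarray],
        y: np.ndarray,
        X_val: Optional[Sequence[np.ndarray]] = None,
        y_val: Optional[np.ndarray] = None,
    ) -> "ViTRegressor":
        """Train from a seeded random initialisation.

        Raw images are resized/standardised internally; pass per-lung
        targets as ``(n, 2)`` to supervise each head output directly
        (requires ``cutmix=False``).
        """
        y = np.asarray(y, dtype=np.float64)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if len(X) == 0:
            raise ValueError("empty training set")
        images = self._preprocess(X)
        self.network_ = ViTNetwork(self.vit_config(), seed=self.random_state)
        xv = self._preprocess(X_val) if X_val is not None else None
        self.loss_trace_ = train(
            self.network_,
            images,
            y,
            self.train_config(),
            val_images=xv,
            val_targets=y_val,
        )
        self.train_mean_ = float(y.sum(axis=-1).mean() if y.ndim == 2 else y.mean())
        self.n_images_ = len(X)
        return self

    def predict_lungs(self, X: Sequence[np.ndarray]) -> np.ndarray:
        """Per-lung predictions ``(n, 2)``, clamped when configured."""
        check_is_fitted(self, "network_")
        preds = []
        # modest chunks keep peak memory flat on large test sets
        images = self._preprocess(X)
        for start in range(0, len(images), 64):
            preds.append(self.network_.predict_pair(images[start : start + 64]))
        return np.concatenate(preds, axis=0)

    def predict(self, X: Sequence[np.ndarray]) -> np.ndarray:
        """Global severity ``p = p_l + p_r`` per image."""
        return self.predict_lungs(X).sum(axis=1)
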