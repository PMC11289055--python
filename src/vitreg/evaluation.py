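"""Evaluation: MAE, Pearson correlation, CMC curves, error histograms,
and attention-map localisation.

The cumulative matching curve (CMC) reports, for each error threshold
``t``, the fraction of test images whose absolute prediction error is at
most ``t``; it is non-decreasing and reaches 1 once ``t`` covers the
largest error. Attention maps project the transformer's class-token
attention back onto the image, either from the last layer alone or by
attention rollout (chaining head-averaged, residual-corrected attention
across layers).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.transform import resize

from .model import ViTNetwork, attention_rollout

__all__ = [
    "EvalReport",
    "mae",
    "pearson",
    "cmc",
    "attention_map",
    "evaluate",
    "report_from_predictions",
    "save_attention_overlay",
]


def mae(predictions: Sequence[float], targets: Sequence[float]) -> float:
    """Mean absolute error between predicted and annotated scores."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("predictions and targets must have equal length")
    if p.size == 0:
        raise ValueError("cannot compute MAE of an empty set")
    return float(np.mean(np.abs(p - t)))


def pearson(predictions: Sequence[float], targets: Sequence[float]) -> float:
    """Product-moment correlation; ``nan`` (with a warning) when either
    side has zero variance, where the coefficient is undefined."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("predictions and targets must have equal length")
    if p.size < 2:
        raise ValueError("Pearson correlation needs at least two points")
    if p.std() == 0.0 or t.std() == 0.0:
        warnings.warn(
            "Pearson correlation undefined for zero-variance input",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(p, t)[0, 1])


def cmc(
    abs_errors: Sequence[float], thresholds: Sequence[float]
) -> List[Tuple[float, float]]:
    """Fraction of images with absolute error <= each threshold."""
    errors = np.asarray(abs_errors, dtype=np.float64)
    thr = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(thr) < 0):
        raise ValueError("thresholds must be sorted ascending")
    n = max(errors.size, 1)
    return [(float(t), float((errors <= t).sum() / n)) for t in thr]


@dataclass
class EvalReport:
    """Aggregated regression metrics over a test set.

    ``pearson_defined`` is False when either side had zero variance
    (e.g. a constant predictor), in which case ``pearson`` is ``nan``.
    """

    mae: float
    pearson: float
    pearson_defined: bool
    abs_errors: List[float]
    cmc: List[Tuple[float, float]]
    histogram_edges: List[float]
    histogram_counts: List[int]

    def to_dict(self) -> Dict:
        return {
            "mae": self.mae,
            "pearson": None if not self.pearson_defined else self.pearson,
            "pearson_defined": self.pearson_defined,
            "n": len(self.abs_errors),
            "abs_errors": list(map(float, self.abs_errors)),
            "cmc": [[t, f] for t, f in self.cmc],
            "histogram": {
                "edges": list(map(float, self.histogram_edges)),
                "counts": list(map(int, self.histogram_counts)),
            },
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def report_from_predictions(
    predictions: Sequence[float],
    targets: Sequence[float],
    global_max: float = 8.0,
    thresholds: Optional[Sequence[float]] = None,
) -> EvalReport:
    """Build the full report from precomputed global-score predictions.

    The error histogram uses unit-width bins over ``[0, global_max]``;
    CMC thresholds default to half-point steps over the same range.
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty evaluation set")
    errors = np.abs(p - t)
    if thresholds is None:
        thresholds = np.arange(0.5, global_max + 0.5, 0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pc = pearson(p, t) if p.size >= 2 else float("nan")
    edges = np.arange(0.0, global_max + 1.0, 1.0)
    counts, _ = np.histogram(np.clip(errors, 0, global_max), bins=edges)
    return EvalReport(
        mae=mae(p, t),
        pearson=pc,
        pearson_defined=bool(np.isfinite(pc)),
        abs_errors=[float(e) for e in errors],
        cmc=cmc(errors, thresholds),
        histogram_edges=[float(e) for e in edges],
        histogram_counts=[int(c) for c in counts],
    )


def evaluate(
    model,
    X: Sequence[np.ndarray],
    y: Sequence[float],
    global_max: float = 8.0,
    thresholds: Optional[Sequence[float]] = None,
) -> EvalReport:
    """Evaluate a fitted estimator (anything with ``predict``) on images
    ``X`` with annotated global scores ``y``."""
    predictions = model.predict(X)
    return report_from_predictions(predictions, y, global_max, thresholds)


def _network_of(model) -> ViTNetwork:
    if isinstance(model, ViTNetwork):
        return model
    network = getattr(model, "network_", None)
    if network is None:
        raise TypeError("expected a ViTNetwork or a fitted ViTRegressor")
    return network


def attention_map(
    model,
    image: np.ndarray,
    method: str = "rollout",
) -> np.ndarray:
    """Class-token attention projected onto the input image.

    ``image`` must be preprocessed to the model's input size. The patch
    relevances — head-averaged last-layer attention, or rollout across
    all layers — are reshaped to the patch grid, bilinearly upsampled to
    the image size and min-max normalised into ``[0, 1]``.
    """
    network = _network_of(model)
    cfg = network.config
    single = np.asarray(image)
    batch = single[None] if single.ndim in (2, 3) else single
    _, attentions = network.forward(batch, return_attention=True)
    if method == "rollout":
        rel = attention_rollout(attentions)
    elif method == "last_layer_mean":
        rel = attentions[-1].mean(axis=1)[:, 0, 1:]
    else:
        raise ValueError(f"unknown attention method {method!r}")
    g = cfg.grid
    amap = rel[0].reshape(g, g)
    amap = resize(amap, (cfg.image_size, cfg.image_size), order=1, anti_aliasing=False)
    lo, hi = amap.min(), amap.max()
    if hi > lo:
        amap = (amap - lo) / (hi - lo)
    else:
        amap = np.zeros_like(amap)
    return amap


def save_attention_overlay(image: np.ndarray, amap: np.ndarray, path) -> None:
    """Write a PNG of the image with the attention map alpha-blended."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img, cmap="gray", interpolation="nearest")
    ax.imshow(amap, cmap="jet", alpha=0.4, interpolation="bilinear")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
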