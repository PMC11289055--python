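"""Vision-transformer severity regressor: forward pass, gradients, configs.

The network is the standard non-hierarchical ViT: the input image is cut
into ``P x P`` patches, each flattened and linearly projected to a
``D``-dimensional token, a learned class token is prepended and learned
position embeddings are added,

    z_0 = [CLS; x_p^1 E; ...; x_p^N E] + E_pos,

then ``L`` pre-norm encoder layers are applied,

    z'_l = MSA(LN(z_{l-1})) + z_{l-1},
    z_l  = MLP(LN(z'_l))   + z'_l,

and a two-layer regression head maps the final-layer class token to a
pair of scores ``(p_l, p_r)``, one per lung. The global severity
prediction is their sum ``p = p_l + p_r``; with clamped heads each
per-lung score is limited to ``[0, 4]`` so ``p`` lies in ``[0, 8]``.

Everything — forward pass, backpropagation, parameter initialisation —
is implemented directly on NumPy arrays; gradients are exact (they are
checked against finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import erf

__all__ = [
    "ViTConfig",
    "TINY",
    "SMALL",
    "NANO",
    "ViTNetwork",
    "patchify",
    "unpatchify",
    "param_shapes",
    "count_parameters",
    "attention_rollout",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ViTConfig:
    """Architecture hyperparameters.

    Defaults are the tiny-ViT setting used for 224x224 radiographs:
    patch 16, depth 12, width 192, 3 heads, MLP ratio 4, and a 128-unit
    hidden layer feeding the 2-unit (left/right lung) output.
    """

    image_size: int = 224
    channels: int = 3
    patch_size: int = 16
    depth: int = 12
    embed_dim: int = 192
    num_heads: int = 3
    mlp_ratio: float = 4.0
    head_hidden: int = 128
    head_out: int = 2
    head_activation: str = "none"  # "none" | "relu" | "gelu"
    per_lung_max: float = 4.0
    clamp_output: bool = True

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        if self.head_out != 2:
            raise ValueError("the regression head has exactly two outputs")
        if self.head_activation not in ("none", "relu", "gelu"):
            raise ValueError(f"unknown head_activation {self.head_activation!r}")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid * self.grid

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * self.channels

    @property
    def mlp_dim(self) -> int:
        return int(self.embed_dim * self.mlp_ratio)

    @property
    def global_max(self) -> float:
        return 2.0 * self.per_lung_max


#: Tiny backbone for 224x224 inputs (the benchmark configuration).
TINY = ViTConfig()
#: Small backbone: same layout at width 384 / 6 heads.
SMALL = ViTConfig(embed_dim=384, num_heads=6)
#: Nano backbone for 64x64 inputs; desk-scale experiments and tests.
NANO = ViTConfig(image_size=64, patch_size=8, depth=4, embed_dim=64, num_heads=2)


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut ``(B, H, W, C)`` images into row-major flattened patches.

    Returns ``(B, N, P*P*C)`` with ``N = H*W/P**2``; patch order runs
    top-left to bottom-right.
    """
    if images.ndim == 3:
        images = images[..., None]
    b, h, w, c = images.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image dims ({h}, {w}) not divisible by patch size {p}")
    x = images.reshape(b, h // p, p, w // p, p, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, (h // p) * (w // p), p * p * c)


def unpatchify(patches: np.ndarray, image_shape: Tuple[int, ...], patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` (bit-exact)."""
    h, w = image_shape[0], image_shape[1]
    c = image_shape[2] if len(image_shape) > 2 else 1
    p = patch_size
    b = patches.shape[0]
    x = patches.reshape(b, h // p, w // p, p, p, c)
    x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h, w, c)
    return x if len(image_shape) > 2 else x[..., 0]


def param_shapes(config: ViTConfig) -> Dict[str, Tuple[int, ...]]:
    """Name -> shape of every trainable tensor, in a fixed order."""
    d, pd, md = config.embed_dim, config.patch_dim, config.mlp_dim
    shapes: Dict[str, Tuple[int, ...]] = {
        "patch/W": (pd, d),
        "patch/b": (d,),
        "cls": (d,),
        "pos": (config.num_patches + 1, d),
    }
    for l in range(config.depth):
        shapes.update(
            {
                f"blk{l}/ln1/g": (d,),
                f"blk{l}/ln1/b": (d,),
                f"blk{l}/qkv/W": (d, 3 * d),
                f"blk{l}/qkv/b": (3 * d,),
                f"blk{l}/proj/W": (d, d),
                f"blk{l}/proj/b": (d,),
                f"blk{l}/ln2/g": (d,),
                f"blk{l}/ln2/b": (d,),
                f"blk{l}/fc1/W": (d, md),
                f"blk{l}/fc1/b": (md,),
                f"blk{l}/fc2/W": (md, d),
                f"blk{l}/fc2/b": (d,),
            }
        )
    shapes.update(
        {
            "norm/g": (d,),
            "norm/b": (d,),
            "head/W1": (d, config.head_hidden),
            "head/b1": (config.head_hidden,),
            "head/W2": (config.head_hidden, config.head_out),
            "head/b2": (config.head_out,),
        }
    )
    return shapes


def count_parameters(config: ViTConfig) -> int:
    """Exact number of trainable scalars in the architecture."""
    return int(sum(int(np.prod(s)) for s in param_shapes(config).values()))


def init_params(
    config: ViTConfig, rng: np.random.Generator, dtype=np.float32
) -> Dict[str, np.ndarray]:
    """Seeded initialisation: N(0, 0.02) weights/embeddings, zero biases,
    unit LayerNorm gains."""
    params: Dict[str, np.ndarray] = {}
    for name, shape in param_shapes(config).items():
        if name.endswith("/g") or name == "norm/g":
            params[name] = np.ones(shape, dtype=dtype)
        elif name.endswith("/b") or name.endswith("b1") or name.endswith("b2"):
            params[name] = np.zeros(shape, dtype=dtype)
        elif name in ("cls", "pos") or name.endswith("W") or "W" in name.split("/")[-1]:
            params[name] = (rng.standard_normal(shape) * 0.02).astype(dtype)
        else:  # pragma: no cover - all names matched above
            params[name] = np.zeros(shape, dtype=dtype)
    return params


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _ln_forward(x, g, b, eps=1e-6):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(-1, keepdims=True) + eps)
    xn = xc * inv
    return g * xn + b, (xn, inv, g)


def _ln_backward(dy, cache):
    xn, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xn).sum(axes)
    db = dy.sum(axes)
    dxn = dy * g
    dx = inv * (
        dxn
        - dxn.mean(-1, keepdims=True)
        - xn * (dxn * xn).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _linear_grads(x, dy):
    # x: (..., in), dy: (..., out) -> dW (in, out), db (out,)
    dw = np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
    db = dy.sum(tuple(range(dy.ndim - 1)))
    return dw, db


class ViTNetwork:
    """The regressor network over a NumPy parameter dictionary.

    Parameters live in :attr:`params`, keyed as in :func:`param_shapes`;
    :meth:`forward` evaluates the head outputs, :meth:`backward`
    propagates a gradient w.r.t. those outputs into a gradient
    dictionary with identical keys.
    """

    def __init__(
        self,
        config: ViTConfig,
        seed: int = 0,
        params: Optional[Dict[str, np.ndarray]] = None,
        dtype=np.float32,
    ) -> None:
        self.config = config
        self.dtype = dtype
        if params is None:
            params = init_params(config, np.random.default_rng(seed), dtype)
        self.params = params

    # ------------------------------------------------------------------
    def forward(
        self,
        images: np.ndarray,
        return_cache: bool = False,
        return_attention: bool = False,
    ):
        """Head outputs ``(B, 2)`` for preprocessed images ``(B, H, W, C)``.

        With ``return_cache`` the activation cache needed by
        :meth:`backward` is returned; with ``return_attention`` the
        per-layer attention tensors ``(B, heads, T, T)`` are returned.
        """
        cfg, P = self.config, self.params
        images = np.asarray(images, dtype=self.dtype)
        if images.ndim == 3:
            images = images[..., None]
        if images.shape[1] != cfg.image_size or images.shape[2] != cfg.image_size:
            raise ValueError(
                f"expected {cfg.image_size}x{cfg.image_size} input, "
                f"got {images.shape[1]}x{images.shape[2]}"
            )
        if images.shape[3] != cfg.channels:
            raise ValueError(f"expected {cfg.channels} channels")
        x = patchify(images, cfg.patch_size)  # (B, N, pd)
        b = x.shape[0]
        t = x @ P["patch/W"] + P["patch/b"]
        cls = np.broadcast_to(P["cls"], (b, 1, cfg.embed_dim))
        z = np.concatenate([cls, t], axis=1) + P["pos"]

        nh, dh = cfg.num_heads, cfg.embed_dim // cfg.num_heads
        scale = 1.0 / np.sqrt(dh)
        layer_caches = []
        attentions: List[np.ndarray] = []
        for l in range(cfg.depth):
            h, ln1c = _ln_forward(z, P[f"blk{l}/ln1/g"], P[f"blk{l}/ln1/b"])
            qkv = h @ P[f"blk{l}/qkv/W"] + P[f"blk{l}/qkv/b"]
            T = qkv.shape[1]
            qkv_h = qkv.reshape(b, T, 3, nh, dh).transpose(2, 0, 3, 1, 4)
            q, k, v = qkv_h[0], qkv_h[1], qkv_h[2]  # (B, nh, T, dh)
            s = (q @ k.transpose(0, 1, 3, 2)) * scale
            s -= s.max(-1, keepdims=True)
            a = np.exp(s)
            a /= a.sum(-1, keepdims=True)
            if return_attention:
                attentions.append(a)
            o = a @ v  # (B, nh, T, dh)
            o_m = o.transpose(0, 2, 1, 3).reshape(b, T, cfg.embed_dim)
            y = o_m @ P[f"blk{l}/proj/W"] + P[f"blk{l}/proj/b"]
            z_mid = z + y
            h2, ln2c = _ln_forward(z_mid, P[f"blk{l}/ln2/g"], P[f"blk{l}/ln2/b"])
            u = h2 @ P[f"blk{l}/fc1/W"] + P[f"blk{l}/fc1/b"]
            gact = _gelu(u)
            m = gact @ P[f"blk{l}/fc2/W"] + P[f"blk{l}/fc2/b"]
            z_next = z_mid + m
            if return_cache:
                layer_caches.append((h, ln1c, a, v, q, k, o_m, z, h2, ln2c, u, gact))
            z = z_next

        hn, lnfc = _ln_forward(z, P["norm/g"], P["norm/b"])
        cls_out = hn[:, 0]
        h1 = cls_out @ P["head/W1"] + P["head/b1"]
        if cfg.head_activation == "relu":
            a1 = np.maximum(h1, 0.0)
        elif cfg.head_activation == "gelu":
            a1 = _gelu(h1)
        else:
            a1 = h1
        out = a1 @ P["head/W2"] + P["head/b2"]

        result = [out]
        if return_cache:
            result.append(
                {
                    "x": x,
                    "layers": layer_caches,
                    "lnf": lnfc,
                    "cls_out": cls_out,
                    "h1": h1,
                    "a1": a1,
                    "ntok": z.shape[1],
                }
            )
        if return_attention:
            result.append(attentions)
        return result[0] if len(result) == 1 else tuple(result)

    # ------------------------------------------------------------------
    def backward(self, dout: np.ndarray, cache: Dict) -> Dict[str, np.ndarray]:
        """Gradients of ``sum(dout * out)`` w.r.t. every parameter."""
        cfg, P = self.config, self.params
        grads: Dict[str, np.ndarray] = {}
        b = dout.shape[0]
        nh, dh = cfg.num_heads, cfg.embed_dim // cfg.num_heads
        scale = 1.0 / np.sqrt(dh)
        T = cache["ntok"]

        a1, h1, cls_out = cache["a1"], cache["h1"], cache["cls_out"]
        grads["head/W2"], grads["head/b2"] = _linear_grads(a1, dout)
        da1 = dout @ P["head/W2"].T
        if cfg.head_activation == "relu":
            dh1 = da1 * (h1 > 0)
        elif cfg.head_activation == "gelu":
            dh1 = da1 * _gelu_grad(h1)
        else:
            dh1 = da1
        grads["head/W1"], grads["head/b1"] = _linear_grads(cls_out, dh1)
        dcls = dh1 @ P["head/W1"].T

        dhn = np.zeros((b, T, cfg.embed_dim), dtype=self.dtype)
        dhn[:, 0] = dcls
        dz, grads["norm/g"], grads["norm/b"] = _ln_backward(dhn, cache["lnf"])

        for l in reversed(range(cfg.depth)):
            h, ln1c, a, v, q, k, o_m, z_in, h2, ln2c, u, gact = cache["layers"][l]
            # MLP branch
            dm = dz
            grads[f"blk{l}/fc2/W"], grads[f"blk{l}/fc2/b"] = _linear_grads(gact, dm)
            dg = dm @ P[f"blk{l}/fc2/W"].T
            du = dg * _gelu_grad(u)
            grads[f"blk{l}/fc1/W"], grads[f"blk{l}/fc1/b"] = _linear_grads(h2, du)
            dh2 = du @ P[f"blk{l}/fc1/W"].T
            dz_mid_ln, grads[f"blk{l}/ln2/g"], grads[f"blk{l}/ln2/b"] = _ln_backward(
                dh2, ln2c
            )
            dz_mid = dz + dz_mid_ln
            # attention branch
            dy = dz_mid
            grads[f"blk{l}/proj/W"], grads[f"blk{l}/proj/b"] = _linear_grads(o_m, dy)
            do_m = dy @ P[f"blk{l}/proj/W"].T
            do = do_m.reshape(b, T, nh, dh).transpose(0, 2, 1, 3)
            dA = do @ v.transpose(0, 1, 3, 2)
            dv = a.transpose(0, 1, 3, 2) @ do
            ds = a * (dA - (dA * a).sum(-1, keepdims=True))
            dq = (ds @ k) * scale
            dk = (ds.transpose(0, 1, 3, 2) @ q) * scale
            dqkv = np.empty((3, b, nh, T, dh), dtype=self.dtype)
            dqkv[0], dqkv[1], dqkv[2] = dq, dk, dv
            dqkv_m = dqkv.transpose(1, 3, 0, 2, 4).reshape(b, T, 3 * cfg.embed_dim)
            grads[f"blk{l}/qkv/W"], grads[f"blk{l}/qkv/b"] = _linear_grads(h, dqkv_m)
            dhh = dqkv_m @ P[f"blk{l}/qkv/W"].T
            dz_ln, grads[f"blk{l}/ln1/g"], grads[f"blk{l}/ln1/b"] = _ln_backward(
                dhh, ln1c
            )
            dz = dz_mid + dz_ln

        grads["pos"] = dz.sum(0)
        grads["cls"] = dz[:, 0].sum(0)
        dt = dz[:, 1:]
        grads["patch/W"], grads["patch/b"] = _linear_grads(cache["x"], dt)
        return grads

    # ------------------------------------------------------------------
    def predict_pair(
        self, images: np.ndarray, clamp: Optional[bool] = None
    ) -> np.ndarray:
        """Per-lung predictions ``(B, 2)``; clamped to ``[0, 4]`` when enabled."""
        out = self.forward(images)
        clamp = self.config.clamp_output if clamp is None else clamp
        if clamp:
            out = np.clip(out, 0.0, self.config.per_lung_max)
        return out

    def predict_global(
        self, images: np.ndarray, clamp: Optional[bool] = None
    ) -> np.ndarray:
        """Global severity ``p = p_l + p_r`` per image."""
        return self.predict_pair(images, clamp=clamp).sum(axis=1)

    def num_parameters(self) -> int:
        return count_parameters(self.config)


def attention_rollout(attentions: List[np.ndarray]) -> np.ndarray:
    """Aggregate per-layer attentions into CLS-to-patch relevance.

    Each layer's head-averaged attention is mixed with the identity
    (residual correction), row-normalised, and the layers are chained by
    matrix product. Returns ``(B, N)`` relevances of the class token
    over the patch tokens.
    """
    if not attentions:
        raise ValueError("no attention matrices supplied")
    b, _, t, _ = attentions[0].shape
    rollout = np.broadcast_to(np.eye(t), (b, t, t)).copy()
    eye = np.eye(t)
    for a in attentions:
        am = a.mean(axis=1) + eye
        am /= am.sum(-1, keepdims=True)
        rollout = am @ rollout
    return rollout[:, 0, 1:]
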