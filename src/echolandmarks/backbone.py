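"""Segmentation backbone: a small encoder-decoder heatmap network.

The meta-learning layer is model-agnostic: it only requires a model object
exposing ``loss_and_grad(params, batch)`` plus a body/head partition of the
parameters.  This module provides that contract together with one concrete
reference network -- a 3-level encoder-decoder with skip connections
(a miniature U-Net) implemented directly on NumPy arrays with explicit
forward/backward passes, small enough to meta-train on a single CPU.

Parameters are stored as ``ModelParams``: two ordered name->array mappings,
``body`` (the shared representation, adapted by every learner except ANIL's
inner loop) and ``head`` (the final 1x1 projection to the 4 landmark
channels, the only part ANIL adapts per task).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ParamDict = "OrderedDict[str, np.ndarray]"


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Trainable parameters partitioned into a shared body and a task head."""

    body: OrderedDict = field(default_factory=OrderedDict)
    head: OrderedDict = field(default_factory=OrderedDict)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        yield from self.body.items()
        yield from self.head.items()

    def names(self) -> list[str]:
        return list(self.body) + list(self.head)

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.body:
            return self.body[name]
        return self.head[name]

    def is_head(self, name: str) -> bool:
        return name in self.head

    def n_parameters(self) -> int:
        return sum(int(v.size) for _, v in self.items())

    def copy(self) -> "ModelParams":
        return ModelParams(
            body=OrderedDict((k, v.copy()) for k, v in self.body.items()),
            head=OrderedDict((k, v.copy()) for k, v in self.head.items()),
        )

    def replace(self, updates: dict) -> "ModelParams":
        """New ModelParams with some tensors replaced (others shared copies)."""
        out = self.copy()
        for k, v in updates.items():
            if k in out.body:
                out.body[k] = np.asarray(v, dtype=out.body[k].dtype)
            elif k in out.head:
                out.head[k] = np.asarray(v, dtype=out.head[k].dtype)
            else:
                raise KeyError(f"unknown parameter {k!r}")
        return out

    def allclose(self, other: "ModelParams", rtol=1e-12, atol=1e-12) -> bool:
        return self.names() == other.names() and all(
            np.allclose(self[k], other[k], rtol=rtol, atol=atol) for k in self.names()
        )


def clone_params(params: ModelParams) -> ModelParams:
    """Deep, independent copy; mutating the clone never touches the original."""
    return params.copy()


# ---------------------------------------------------------------------------
# layer primitives (explicit forward/backward)
# ---------------------------------------------------------------------------

def _conv2d(x, w, b, pad):
    # x: (B, C, H, W); w: (Co, C, kh, kw)
    kh, kw = w.shape[2], w.shape[3]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (B,C,H,W,kh,kw)
    out = np.einsum("bchwij,ocij->bohw", win, w, optimize=True)
    return out + b[None, :, None, None]


def _conv2d_backward(x, w, dout, pad):
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    dw = np.einsum("bchwij,bohw->ocij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    # grad wrt input: full correlation with the flipped kernel
    fp = kh - 1 - pad
    dp = np.pad(dout, ((0, 0), (0, 0), (fp, fp), (fp, fp))) if fp else dout
    dwin = sliding_window_view(dp, (kh, kw), axis=(2, 3))
    wf = w[:, :, ::-1, ::-1]
    dx = np.einsum("bohwij,ocij->bchw", dwin, wf, optimize=True)
    return dx, dw, db


LEAK = 0.01  # leaky-ReLU slope: keeps gradients alive through adaptation


def _lrelu(z):
    return np.where(z > 0, z, LEAK * z)


def _lrelu_mask(a):
    # a is the activation; a > 0 iff the pre-activation was > 0
    return np.where(a > 0, 1.0, LEAK).astype(a.dtype)


def _pool2(x):
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_backward(dout):
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_backward(dout):
    b, c, h, w = dout.shape
    return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# the reference network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of the reference encoder-decoder.

    width is the base channel count; the encoder doubles it once.  Input
    images must be square with side divisible by 4 (two pooling levels).
    """

    in_channels: int = 1
    out_channels: int = 4
    width: int = 4
    image_size: int = 64
    dtype: str = "float32"  # float32 is ~4x faster on CPU; float64 for checks

    def __post_init__(self):
        if self.width < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel widths must be positive")
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class HeatmapNet:
    """3-level encoder-decoder with skip connections, returning C heatmaps.

    Purely functional: ``forward(params, x)`` never mutates state, so the
    same parameters and input always give bit-identical output.
    """

    def __init__(self, config: BackboneConfig | None = None):
        self.config = config or BackboneConfig()

    # -- initialisation -----------------------------------------------------

    def init_params(self, rng_seed: int) -> ModelParams:
        cfg = self.config
        rng = np.random.default_rng(rng_seed)
        w = cfg.width
        dt = cfg.np_dtype

        def he(co, ci, k):
            fan_in = ci * k * k
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(co, ci, k, k)).astype(dt)

        body = OrderedDict()
        body["enc1.w"] = he(w, cfg.in_channels, 3)
        body["enc1.b"] = np.zeros(w, dtype=dt)
        body["enc2.w"] = he(2 * w, w, 3)
        body["enc2.b"] = np.zeros(2 * w, dtype=dt)
        body["bott.w"] = he(2 * w, 2 * w, 3)
        body["bott.b"] = np.zeros(2 * w, dtype=dt)
        body["dec2.w"] = he(w, 4 * w, 3)
        body["dec2.b"] = np.zeros(w, dtype=dt)
        body["dec1.w"] = he(w, 2 * w, 3)
        body["dec1.b"] = np.zeros(w, dtype=dt)
        head = OrderedDict()
        head["head.w"] = he(cfg.out_channels, w, 1)
        head["head.b"] = np.zeros(cfg.out_channels, dtype=dt)
        return ModelParams(body=body, head=head)

    def expected_n_parameters(self) -> int:
        """Closed-form parameter count for the configured widths."""
        w, ci, co = self.config.width, self.config.in_channels, self.config.out_channels
        n = w * ci * 9 + w            # enc1
        n += 2 * w * w * 9 + 2 * w    # enc2
        n += 2 * w * 2 * w * 9 + 2 * w  # bottleneck
        n += w * 4 * w * 9 + w        # dec2
        n += w * 2 * w * 9 + w        # dec1
        n += co * w + co              # head 1x1
        return n

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.config.np_dtype)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (B,{self.config.in_channels},H,W) input, got {x.shape}")
        if x.shape[2] != self.config.image_size or x.shape[3] != self.config.image_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match configured "
                f"{self.config.image_size}"
            )
        return x

    def _forward_cached(self, p: ModelParams, x: np.ndarray):
        x0 = x / 255.0  # images arrive normalised to [0,255]
        a1 = _lrelu(_conv2d(x0, p["enc1.w"], p["enc1.b"], 1))
        p1 = _pool2(a1)
        a2 = _lrelu(_conv2d(p1, p["enc2.w"], p["enc2.b"], 1))
        p2 = _pool2(a2)
        a3 = _lrelu(_conv2d(p2, p["bott.w"], p["bott.b"], 1))
        u2 = _up2(a3)
        c2 = np.concatenate([u2, a2], axis=1)
        a4 = _lrelu(_conv2d(c2, p["dec2.w"], p["dec2.b"], 1))
        u1 = _up2(a4)
        c1 = np.concatenate([u1, a1], axis=1)
        a5 = _lrelu(_conv2d(c1, p["dec1.w"], p["dec1.b"], 1))
        y = _conv2d(a5, p["head.w"], p["head.b"], 0)
        cache = (x0, a1, p1, a2, p2, a3, c2, a4, c1, a5)
        return y, cache

    def forward(self, params: ModelParams, x: np.ndarray) -> np.ndarray:
        """Predict heatmaps: (B, C, H, W), C landmark channels."""
        x = self._check_input(x)
        y, _ = self._forward_cached(params, x)
        return y

    def loss_and_grad(self, params: ModelParams, batch) -> tuple[float, OrderedDict]:
        """MSE heatmap loss and its gradient w.r.t. every parameter.

        batch = (images, target_heatmaps); targets shaped (B, C, H, W).
        """
        x, t = batch
        x = self._check_input(x)
        t = np.asarray(t, dtype=self.config.np_dtype)
        if t.shape != (x.shape[0], self.config.out_channels, x.shape[2], x.shape[3]):
            raise ValueError(f"target shape {t.shape} mismatches input {x.shape}")
        p = params
        y, (x0, a1, p1, a2, p2, a3, c2, a4, c1, a5) = self._forward_cached(p, x)
        diff = y - t
        loss = float(np.mean(diff * diff))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss in backbone")
        g = OrderedDict()
        dy = 2.0 * diff / diff.size
        da5, g["head.w"], g["head.b"] = _conv2d_backward(a5, p["head.w"], dy, 0)
        da5 *= _lrelu_mask(a5)
        dc1, g["dec1.w"], g["dec1.b"] = _conv2d_backward(c1, p["dec1.w"], da5, 1)
        w_ = self.config.width
        du1, da1_skip = dc1[:, :w_], dc1[:, w_:]
        da4 = _up2_backward(du1)
        da4 *= _lrelu_mask(a4)
        dc2, g["dec2.w"], g["dec2.b"] = _conv2d_backward(c2, p["dec2.w"], da4, 1)
        du2, da2_skip = dc2[:, : 2 * w_], dc2[:, 2 * w_:]
        da3 = _up2_backward(du2)
        da3 *= _lrelu_mask(a3)
        dp2, g["bott.w"], g["bott.b"] = _conv2d_backward(p2, p["bott.w"], da3, 1)
        da2 = _pool2_backward(dp2) + da2_skip
        da2 *= _lrelu_mask(a2)
        dp1, g["enc2.w"], g["enc2.b"] = _conv2d_backward(p1, p["enc2.w"], da2, 1)
        da1 = _pool2_backward(dp1) + da1_skip
        da1 *= _lrelu_mask(a1)
        _, g["enc1.w"], g["enc1.b"] = _conv2d_backward(x0, p["enc1.w"], da1, 1)
        # reorder to match the parameter ordering
        ordered = OrderedDict((k, g[k]) for k in params.names())
        return loss, ordered


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_params(params: ModelParams, path) -> None:
    """Serialise parameters with the body/head partition preserved."""
    arrays = {f"body::{k}": v for k, v in params.body.items()}
    arrays.update({f"head::{k}": v for k, v in params.head.items()})
    np.savez(path, **arrays)


def load_params(path) -> ModelParams:
    data = np.load(path)
    body, head = OrderedDict(), OrderedDict()
    for key in data.files:
        part, name = key.split("::", 1)
        (body if part == "body" else head)[name] = data[key]
    return ModelParams(body=body, head=head)
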