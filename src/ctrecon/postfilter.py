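"""Learned convolutional post-filter for reconstructed images.

A single-channel convolution layer T(x) = d(H * x + p) — kernel H, scalar
bias p, elementwise activation d — trained by gradient descent with
momentum to map degraded reconstructions toward their ground-truth images
under a mean-squared-error loss.  One layer is deliberate: it is the
minimal network realizing the feature-map/update equations this package
implements, and its least-squares training problem (identity activation)
has a verifiable analytic gradient.

The standard momentum update is

    v <- beta * v - lr * grad,    H <- H + v,

with the bias carrying its own scalar velocity.  A ``literal_update`` mode
replaces the velocity by ``beta * H - lr * grad`` (momentum applied to the
kernel itself rather than to past gradients); that variant diverges for
beta > 0 and exists only for demonstration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .geometry import ImageGrid

__all__ = ["KernelState", "conv_forward", "momentum_update", "train_postfilter", "loss_and_gradients"]


@dataclass
class KernelState:
    """Convolution kernel, bias, momentum buffers and hyperparameters."""

    kernel: np.ndarray
    bias: float = 0.0
    velocity: np.ndarray | None = None
    bias_velocity: float = 0.0
    beta: float = 0.9
    lr: float = 0.1
    activation: str = "identity"

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        k = self.kernel.shape[0]
        if self.kernel.ndim != 2 or self.kernel.shape != (k, k):
            raise ValueError("kernel must be square")
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        if not 0 <= self.beta < 1:
            raise ValueError("beta must lie in [0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.activation not in ("identity", "relu"):
            raise ValueError("activation must be 'identity' or 'relu'")
        if self.velocity is None:
            self.velocity = np.zeros_like(self.kernel)
        else:
            self.velocity = np.asarray(self.velocity, dtype=float)
            if self.velocity.shape != self.kernel.shape:
                raise ValueError("velocity must match kernel shape")

    @classmethod
    def identity(cls, k: int = 3, **kw) -> "KernelState":
        h = np.zeros((k, k))
        h[k // 2, k // 2] = 1.0
        return cls(kernel=h, **kw)

    @classmethod
    def random(cls, k: int = 3, scale: float = 0.1, seed: int = 0, **kw) -> "KernelState":
        rng = np.random.default_rng(seed)
        return cls(kernel=scale * rng.standard_normal((k, k)), **kw)

    def copy(self) -> "KernelState":
        return KernelState(
            kernel=self.kernel.copy(),
            bias=self.bias,
            velocity=self.velocity.copy(),
            bias_velocity=self.bias_velocity,
            beta=self.beta,
            lr=self.lr,
            activation=self.activation,
        )

    # --- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": self.kernel.tolist(),
                "bias": self.bias,
                "velocity": self.velocity.tolist(),
                "bias_velocity": self.bias_velocity,
                "beta": self.beta,
                "lr": self.lr,
                "activation": self.activation,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KernelState":
        doc = json.loads(text)
        return cls(
            kernel=np.array(doc["kernel"]),
            bias=doc["bias"],
            velocity=np.array(doc["velocity"]),
            bias_velocity=doc["bias_velocity"],
            beta=doc["beta"],
            lr=doc["lr"],
            activation=doc["activation"],
        )


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "identity":
        return z
    return np.maximum(z, 0.0)


def conv_forward(x: ImageGrid | np.ndarray, ks: KernelState) -> ImageGrid | np.ndarray:
    """Apply the layer: cross-correlation with reflection padding, bias, activation."""
    arr = x.pixels if isinstance(x, ImageGrid) else np.asarray(x, dtype=float)
    if ks.kernel.shape[0] > min(arr.shape):
        raise ValueError("kernel larger than image")
    z = correlate(arr, ks.kernel, mode="reflect") + ks.bias
    out = _activate(z, ks.activation)
    if isinstance(x, ImageGrid):
        return ImageGrid(out, x.pixel_size)
    return out


def momentum_update(
    ks: KernelState,
    grad: np.ndarray,
    bias_grad: float = 0.0,
    *,
    literal_update: bool = False,
) -> KernelState:
    """One momentum step on the kernel (and bias); returns a new state.

    Standard form: velocity <- beta*velocity - lr*grad; kernel += velocity.
    ``literal_update`` uses beta times the kernel itself in place of the
    velocity — kept only to demonstrate that that rule diverges.
    """
    grad = np.asarray(grad, dtype=float)
    if grad.shape != ks.kernel.shape:
        raise ValueError("gradient shape must match kernel")
    if not (np.all(np.isfinite(grad)) and np.isfinite(bias_grad)):
        raise ValueError("non-finite gradient")
    out = ks.copy()
    if literal_update:
        step = ks.beta * ks.kernel - ks.lr * grad
        out.velocity = step
        out.kernel = ks.kernel + step
        bstep = ks.beta * ks.bias - ks.lr * bias_grad
        out.bias_velocity = bstep
        out.bias = ks.bias + bstep
    else:
        out.velocity = ks.beta * ks.velocity - ks.lr * grad
        out.kernel = ks.kernel + out.velocity
        out.bias_velocity = ks.beta * ks.bias_velocity - ks.lr * bias_grad
        out.bias = ks.bias + out.bias_velocity
    return out


def loss_and_gradients(
    x: np.ndarray, y: np.ndarray, ks: KernelState
) -> tuple[float, np.ndarray, float]:
    """MSE loss and its analytic gradients w.r.t. kernel and bias.

    With reflection padding, d out[i,j] / d H[u,v] = x_pad[i+u, j+v]; the
    kernel gradient is the residual-weighted sum of those sliding windows
    (a subgradient through relu, gating on the pre-activation sign).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pair images must share a shape")
    k = ks.kernel.shape[0]
    half = k // 2
    # ndimage's 'reflect' boundary is edge-inclusive, i.e. np.pad 'symmetric'
    x_pad = np.pad(x, half, mode="symmetric")
    z = correlate(x, ks.kernel, mode="reflect") + ks.bias
    out = _activate(z, ks.activation)
    resid = out - y
    loss = float(np.mean(resid**2))
    gate = resid if ks.activation == "identity" else resid * (z > 0)
    npix = x.size
    windows = np.lib.stride_tricks.sliding_window_view(x_pad, (k, k))
    grad_h = 2.0 / npix * np.einsum("ij,ijuv->uv", gate, windows)
    grad_b = float(2.0 / npix * gate.sum())
    return loss, grad_h, grad_b


def train_postfilter(
    pairs: list[tuple[ImageGrid | np.ndarray, ImageGrid | np.ndarray]],
    ks0: KernelState,
    epochs: int = 100,
    seed: int = 0,
) -> tuple[KernelState, np.ndarray]:
    """Train the post-filter on (degraded, clean) pairs by momentum SGD.

    One gradient step per pair per epoch, pair order reshuffled with the
    seeded generator each epoch; returns the final state and the per-epoch
    mean loss trace.  Aborts with a diagnostic if the loss goes non-finite
    (learning rate too large).
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    arrays = [
        (
            a.pixels if isinstance(a, ImageGrid) else np.asarray(a, dtype=float),
            b.pixels if isinstance(b, ImageGrid) else np.asarray(b, dtype=float),
        )
        for a, b in pairs
    ]
    for xa, ya in arrays:
        if xa.shape != ya.shape:
            raise ValueError("each pair must share a shape")
    rng = np.random.default_rng(seed)
    ks = ks0.copy()
    trace = np.empty(epochs)
    for ep in range(epochs):
        order = rng.permutation(len(arrays))
        losses = []
        for idx in order:
            xa, ya = arrays[idx]
            loss, grad_h, grad_b = loss_and_gradients(xa, ya, ks)
            losses.append(loss)
            ks = momentum_update(ks, grad_h, grad_b)
        trace[ep] = float(np.mean(losses))
        if not np.isfinite(trace[ep]):
            raise FloatingPointError(
                f"training diverged at epoch {ep} (loss non-finite); lower the learning rate "
                f"(lr={ks.lr}, beta={ks.beta})"
            )
    return ks, trace
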