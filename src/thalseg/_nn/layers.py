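"""3D layers (channel-first, batch-free) with analytic backward passes."""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameters in ``self.params``, gradients in ``self.grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k][...] = 0.0


class Conv3d(Layer):
    """3x3x3 convolution with replicate (edge) padding, stride 1.

    Replicate padding copies border values instead of injecting zeros, so a
    constant input channel stays exactly constant after convolution — the
    property that keeps the coordinate channels' center value 0 unambiguous
    at volume borders.
    """

    KS = 3

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        fan_in = cin * self.KS**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3, 3))
        self.params = {"w": w.astype(DTYPE), "b": np.zeros(cout, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params["w"], self.params["b"]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)), mode="edge")
        self._xp = xp
        _, d, h, wd = x.shape
        y = np.empty((self.cout, d, h, wd), dtype=DTYPE)
        y[:] = b[:, None, None, None]
        for a in range(3):
            for bb in range(3):
                for c in range(3):
                    # (cout,cin) x (cin,d,h,w) contraction per kernel offset
                    y += np.tensordot(
                        w[:, :, a, bb, c],
                        xp[:, a : a + d, bb : bb + h, c : c + wd],
                        axes=([1], [0]),
                    )
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        w = self.params["w"]
        xp = self._xp
        _, d, h, wd = gy.shape
        self.grads["b"] += gy.sum(axis=(1, 2, 3))
        gxp = np.zeros_like(xp)
        gw = self.grads["w"]
        for a in range(3):
            for bb in range(3):
                for c in range(3):
                    sl = np.s_[:, a : a + d, bb : bb + h, c : c + wd]
                    gw[:, :, a, bb, c] += np.tensordot(
                        gy, xp[sl], axes=([1, 2, 3], [1, 2, 3])
                    )
                    gxp[sl] += np.tensordot(w[:, :, a, bb, c], gy, axes=([0], [0]))
        # Adjoint of edge padding: fold the pad ring back onto the border.
        for ax in (1, 2, 3):
            idx = [slice(None)] * 4
            src = [slice(None)] * 4
            idx[ax], src[ax] = 1, 0
            gxp[tuple(idx)] += gxp[tuple(src)]
            idx[ax], src[ax] = -2, -1
            gxp[tuple(idx)] += gxp[tuple(src)]
        return gxp[:, 1:-1, 1:-1, 1:-1]


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial axes with learnable affine."""

    def __init__(self, c: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params = {
            "gamma": np.ones(c, dtype=DTYPE),
            "beta": np.zeros(c, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        g = self.params["gamma"][:, None, None, None]
        b = self.params["beta"][:, None, None, None]
        return (g * self._xhat + b).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.grads["gamma"] += (gy * xhat).sum(axis=(1, 2, 3))
        self.grads["beta"] += gy.sum(axis=(1, 2, 3))
        g = self.params["gamma"][:, None, None, None]
        m = gy[0].size
        gy_mean = gy.mean(axis=(1, 2, 3), keepdims=True)
        gyxhat_mean = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return (g * self._inv_std * (gy - gy_mean - xhat * gyxhat_mean)).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        super().__init__()
        self.slope = negative_slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, self.slope * x).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._pos, gy, self.slope * gy).astype(DTYPE)


class MaxPool3d(Layer):
    """2x2x2 max pooling; ties share the gradient equally (measure-zero case)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"max pooling requires even extents, got {(d, h, w)}")
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(2, 4, 6))
        self._xr_shape = xr.shape
        self._mask = xr == y[:, :, None, :, None, :, None]
        self._tie_count = self._mask.sum(axis=(2, 4, 6), keepdims=True)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gyb = gy[:, :, None, :, None, :, None] / self._tie_count
        gxr = np.where(self._mask, gyb, 0.0).astype(DTYPE)
        c, d2, _, h2, _, w2, _ = self._xr_shape
        return gxr.reshape(c, d2 * 2, h2 * 2, w2 * 2)


def _up_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Double an axis by linear interpolation at half-voxel-aligned samples.

    Output sample 2j sits a quarter voxel below input sample j and 2j+1 a
    quarter voxel above, so out[2j] = 0.25 x[j-1] + 0.75 x[j] and
    out[2j+1] = 0.75 x[j] + 0.25 x[j+1], with edge clamping.
    """
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    down = np.concatenate([x[:1], x[:-1]], axis=0)  # x[j-1], clamped
    up = np.concatenate([x[1:], x[-1:]], axis=0)  # x[j+1], clamped
    out = np.empty((2 * n,) + x.shape[1:], dtype=x.dtype)
    out[0::2] = 0.75 * x + 0.25 * down
    out[1::2] = 0.75 * x + 0.25 * up
    return np.moveaxis(out, 0, axis)


def _up_axis_adjoint(gy: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_up_axis` (verified by dot-product tests)."""
    gy = np.moveaxis(gy, axis, 0)
    ge = gy[0::2]
    go = gy[1::2]
    n = ge.shape[0]
    gx = 0.75 * (ge + go)
    # adjoint of the clamped down-shift in the even taps
    gx[:-1] += 0.25 * ge[1:]
    gx[0] += 0.25 * ge[0]
    # adjoint of the clamped up-shift in the odd taps
    gx[1:] += 0.25 * go[:-1]
    gx[-1] += 0.25 * go[-1]
    return np.moveaxis(gx, 0, axis)


class Upsample2xTrilinear(Layer):
    """Trilinear upsampling with scale factor 2 (separable per-axis)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for ax in (1, 2, 3):
            y = _up_axis(y, ax)
        return y.astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy
        for ax in (3, 2, 1):
            gx = _up_axis_adjoint(gx, ax)
        return gx.astype(DTYPE)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of a (C, D, H, W) volume."""
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=0, keepdims=True)).astype(DTYPE)


def softmax_backward(p: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Gradient through the channel softmax: gz = p * (gp - sum_c gp*p)."""
    dot = (gp * p).sum(axis=0, keepdims=True)
    return (p * (gp - dot)).astype(DTYPE)
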