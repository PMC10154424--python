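"""Minimal 3D convolutional network backend with explicit backpropagation.

A compact, CPU-oriented implementation of the pieces a segmentation U-Net
needs: 3x3x3 convolutions (im2col + matmul), instance normalisation, ELU,
2x max-pooling, nearest-neighbour upsampling with skip concatenation, a 1x1x1
classification head, softmax, and the Adam optimiser. Everything runs in
float32 with channels-first ``(C, D, H, W)`` arrays. Gradients are written
out analytically per layer; caches are only kept while a forward pass is run
in training mode, so inference on larger grids stays memory-light.

The architecture doubles feature maps after every pooling and halves them on
the way up, with skip connections across matching levels. Normalisation is
per-instance (batch size is 1 throughout), which also helps the network cope
with the extreme contrast randomisation of the synthetic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the im2col/col2im data movement when available
    import numba

    @numba.njit(cache=True)
    def _im2col_kernel(xp, cols, d, h, w):  # pragma: no cover - jitted
        c = xp.shape[0]
        for ci in range(c):
            for n in range(27):
                i, j, k = n // 9, (n // 3) % 3, n % 3
                for a in range(d):
                    for b in range(h):
                        for e in range(w):
                            cols[ci, n, a, b, e] = xp[ci, a + i, b + j, e + k]

    @numba.njit(cache=True)
    def _col2im_kernel(dcols, gp, d, h, w):  # pragma: no cover - jitted
        c = gp.shape[0]
        for ci in range(c):
            for n in range(27):
                i, j, k = n // 9, (n // 3) % 3, n % 3
                for a in range(d):
                    for b in range(h):
                        for e in range(w):
                            gp[ci, a + i, b + j, e + k] += dcols[ci, n, a, b, e]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

__all__ = ["ModelConfig", "UNet3D", "Adam", "softmax"]

_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


@dataclass
class ModelConfig:
    """Architecture hyperparameters; the reference model is 5 levels / 24 features."""

    n_levels: int = 3
    first_features: int = 8
    kernel_size: int = 3
    activation: str = "elu"

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.kernel_size != 3:
            raise ValueError("only 3x3x3 kernels are supported")
        if self.activation != "elu":
            raise ValueError("only ELU activations are supported")


def _im2col(x: np.ndarray) -> np.ndarray:
    c, d, h, w = x.shape
    xp = np.zeros((c, d + 2, h + 2, w + 2), dtype=np.float32)
    xp[:, 1:-1, 1:-1, 1:-1] = x
    cols = np.empty((c, 27, d, h, w), dtype=np.float32)
    if _HAVE_NUMBA:
        _im2col_kernel(xp, cols, d, h, w)
    else:
        for n, (i, j, k) in enumerate(_OFFSETS):
            cols[:, n] = xp[:, i:i + d, j:j + h, k:k + w]
    return cols.reshape(c * 27, d * h * w)


def _col2im(dcols: np.ndarray, shape) -> np.ndarray:
    c, d, h, w = shape
    dcols = np.ascontiguousarray(dcols.reshape(c, 27, d, h, w))
    gp = np.zeros((c, d + 2, h + 2, w + 2), dtype=np.float32)
    if _HAVE_NUMBA:
        _col2im_kernel(dcols, gp, d, h, w)
    else:
        for n, (i, j, k) in enumerate(_OFFSETS):
            gp[:, i:i + d, j:j + h, k:k + w] += dcols[:, n]
    return gp[:, 1:-1, 1:-1, 1:-1]


class Conv3d:
    """3x3x3 (or 1x1x1) convolution, stride 1, zero padding, He init."""

    def __init__(self, c_in, c_out, rng, kernel=3, input_layer=False):
        self.kernel = kernel
        self.input_layer = input_layer  # skip the (unused) input gradient
        taps = 27 if kernel == 3 else 1
        std = np.sqrt(2.0 / (c_in * taps))
        self.w = rng.normal(0.0, std, (c_out, c_in * taps)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, train=True):
        c, d, h, w = x.shape
        cols = _im2col(x) if self.kernel == 3 else x.reshape(c, -1)
        y = self.w @ cols + self.b[:, None]
        self._cache = (cols, x.shape) if train else None
        return y.reshape(self.w.shape[0], d, h, w)

    def backward(self, dy):
        cols, xshape = self._cache
        dyf = dy.reshape(dy.shape[0], -1)
        self.dw = dyf @ cols.T
        self.db = dyf.sum(axis=1)
        self._cache = None
        if self.input_layer:
            return None
        dcols = self.w.T @ dyf
        if self.kernel == 3:
            return _col2im(dcols, xshape)
        return dcols.reshape(xshape)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class InstanceNorm:
    """Per-channel normalisation over the spatial grid, learned scale/shift."""

    eps = 1e-5

    def __init__(self, c):
        self.g = np.ones(c, dtype=np.float32)
        self.b = np.zeros(c, dtype=np.float32)
        self.dg = np.zeros_like(self.g)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, train=True):
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv
        y = (self.g[:, None] * xhat + self.b[:, None]).reshape(x.shape)
        self._cache = (xhat, inv, x.shape) if train else None
        return y.astype(np.float32)

    def backward(self, dy):
        xhat, inv, shape = self._cache
        c = shape[0]
        dyf = dy.reshape(c, -1)
        self.dg = (dyf * xhat).sum(axis=1)
        self.db = dyf.sum(axis=1)
        dxhat = dyf * self.g[:, None]
        n = xhat.shape[1]
        dx = inv * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True) / n
        )
        self._cache = None
        return dx.reshape(shape).astype(np.float32)

    def params(self):
        return [(self.g, self.dg), (self.b, self.db)]


class ELU:
    def __init__(self):
        self._cache = None

    def forward(self, x, train=True):
        y = np.where(x > 0, x, np.expm1(x)).astype(np.float32)
        self._cache = (x > 0, y) if train else None
        return y

    def backward(self, dy):
        pos, y = self._cache
        self._cache = None
        return np.where(pos, dy, dy * (y + 1.0)).astype(np.float32)

    def params(self):
        return []


class MaxPool2:
    def __init__(self):
        self._cache = None

    def forward(self, x, train=True):
        c, d, h, w = x.shape
        xr = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        arg = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape) if train else None
        return y

    def backward(self, dy):
        arg, (c, d, h, w) = self._cache
        dxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=-1)
        dx = (
            dxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )
        self._cache = None
        return dx

    def params(self):
        return []


class Upsample2:
    """Centre-aligned trilinear doubling of the spatial grid.

    Output voxel 2k sits a quarter-cell below input voxel k and 2k+1 a
    quarter-cell above, so the 1D weights alternate (0.25, 0.75) and
    (0.75, 0.25) with edge replication; the 3D operator is separable. The
    backward pass is the exact adjoint.
    """

    @staticmethod
    def _up1(x, axis):
        x = np.moveaxis(x, axis, 0)
        lo = np.concatenate([x[:1], x[:-1]], axis=0)   # x[k-1], clamped
        hi = np.concatenate([x[1:], x[-1:]], axis=0)   # x[k+1], clamped
        out = np.empty((2 * x.shape[0],) + x.shape[1:], dtype=x.dtype)
        out[0::2] = 0.75 * x + 0.25 * lo
        out[1::2] = 0.75 * x + 0.25 * hi
        return np.moveaxis(out, 0, axis)

    @staticmethod
    def _down1_adjoint(dy, axis):
        dy = np.moveaxis(dy, axis, 0)
        even, odd = dy[0::2], dy[1::2]
        dx = 0.75 * (even + odd)
        shift_up = np.zeros_like(dx)
        shift_up[:-1] = 0.25 * odd[:-1]   # odd[k] sends 0.25 to x[k+1]
        dx[1:] += shift_up[:-1]
        dx[-1] += 0.25 * odd[-1]          # clamped edge
        shift_dn = np.zeros_like(dx)
        shift_dn[1:] = 0.25 * even[1:]    # even[k] sends 0.25 to x[k-1]
        dx[:-1] += shift_dn[1:]
        dx[0] += 0.25 * even[0]           # clamped edge
        return np.moveaxis(dx, 0, axis)

    def forward(self, x, train=True):
        for axis in (1, 2, 3):
            x = self._up1(x, axis)
        return x.astype(np.float32, copy=False)

    def backward(self, dy):
        for axis in (3, 2, 1):
            dy = self._down1_adjoint(dy, axis)
        return dy.astype(np.float32, copy=False)

    def params(self):
        return []


def _conv_block(c_in, c_out, rng, input_layer=False):
    return [Conv3d(c_in, c_out, rng, input_layer=input_layer),
            InstanceNorm(c_out), ELU(),
            Conv3d(c_out, c_out, rng), InstanceNorm(c_out), ELU()]


class UNet3D:
    """U-shaped encoder/decoder with skip connections and a softmax head."""

    def __init__(self, in_channels: int, n_classes: int, config: ModelConfig,
                 rng: np.random.Generator):
        self.config = config
        self.n_classes = n_classes
        f = config.first_features
        feats = [f * 2 ** i for i in range(config.n_levels)]
        self.down = [
            _conv_block(in_channels if i == 0 else feats[i - 1], feats[i], rng,
                        input_layer=(i == 0))
            for i in range(config.n_levels)
        ]
        self.pools = [MaxPool2() for _ in range(config.n_levels - 1)]
        self.ups = [Upsample2() for _ in range(config.n_levels - 1)]
        # decoder level i: upsample feats[i+1], halve channels with a 1x1
        # conv, concatenate the skip feats[i], then two 3x3x3 convs
        self.reducers = [
            Conv3d(feats[i + 1], feats[i], rng, kernel=1)
            for i in reversed(range(config.n_levels - 1))
        ]
        self.up_blocks = [
            _conv_block(2 * feats[i], feats[i], rng)
            for i in reversed(range(config.n_levels - 1))
        ]
        self.head = Conv3d(feats[0], n_classes, rng, kernel=1)
        self._split_channels = None

    # ---------------------------------------------------------------- passes

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits ``(n_classes, D, H, W)`` for input ``(C, D, H, W)``.

        Spatial dims must be divisible by 2**(n_levels - 1).
        """
        x = x.astype(np.float32, copy=False)
        div = 2 ** (self.config.n_levels - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"spatial dims must be divisible by {div}")
        skips = []
        for i, block in enumerate(self.down):
            for layer in block:
                x = layer.forward(x, train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._split_channels = []
        for i, block in enumerate(self.up_blocks):
            up = self.ups[i].forward(x, train)
            up = self.reducers[i].forward(up, train)
            skip = skips.pop()
            self._split_channels.append(up.shape[0])
            x = np.concatenate([up, skip], axis=0)
            for layer in block:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for i in reversed(range(len(self.up_blocks))):
            for layer in reversed(self.up_blocks[i]):
                dx = layer.backward(dx)
            c_up = self._split_channels[i]
            dup, dskip = dx[:c_up], dx[c_up:]
            dskips.append(dskip)
            dup = self.reducers[i].backward(dup)
            dx = self.ups[i].backward(dup)
        for i in reversed(range(len(self.down))):
            if i < len(self.pools):
                dx = self.pools[i].backward(dx)
                dx = dx + dskips.pop()  # skip connection gradient for level i
            for layer in reversed(self.down[i]):
                dx = layer.backward(dx)

    # ------------------------------------------------------------- utilities

    def _layers(self):
        for block in self.down:
            yield from block
        for reducer, block in zip(self.reducers, self.up_blocks):
            yield reducer
            yield from block
        yield self.head

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for (p, _), w in zip(params, weights):
            p[...] = w

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities without keeping backprop caches."""
        return softmax(self.forward(x, train=False))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, learning_rate=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self, params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(params):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
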