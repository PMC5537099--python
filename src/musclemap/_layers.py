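"""Minimal NumPy building blocks for convolutional segmentation networks.

Forward and backward passes are written against BLAS matmuls via
im2col/col2im, which keeps dense 3x3 convolutions fast enough for CPU
training at phantom scale.  Every layer owns its parameters and, after
``backward``, the exact analytic gradients; the optimizer below is plain
SGD with classical momentum and decoupled-from-nothing L2 weight decay
(decay is added to the gradient, as in standard SGD formulations).

All computations are deterministic for a fixed parameter state and input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ConvTranspose2D",
    "MaxPool2",
    "ReLU",
    "softmax_cross_entropy",
    "SGD",
    "bilinear_kernel",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, ho, wo, k, k), (s0, s1, s2 * stride, s3 * stride, s2, s3)
    )
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )
    return cols, ho, wo


def _col2im(cols, out_shape, k, stride, pad, ho, wo):
    """Scatter-add column gradients back onto the (padded) image grid."""
    n, c, h, w = out_shape
    d = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, i, j
            ]
    return dx[:, :, pad : pad + h, pad : pad + w] if pad else dx


def bilinear_kernel(channels: int, k: int, factor: int, dtype=np.float64) -> np.ndarray:
    """(channels, channels, k, k) transposed-conv weights that perform
    bilinear upsampling by ``factor`` (the classic FCN initialization)."""
    center = (k - 1) / 2.0 if k % 2 == 1 else factor - 0.5
    og = np.ogrid[:k, :k]
    filt = (1 - abs(og[0] - center) / factor) * (1 - abs(og[1] - center) / factor)
    w = np.zeros((channels, channels, k, k), dtype=dtype)
    for i in range(channels):
        w[i, i] = filt
    return w


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}


class Conv2D(Layer):
    """2D convolution (cross-correlation), stride 1+, zero padding."""

    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, init="he", dtype=np.float64):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        if init == "he":
            assert rng is not None
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), (cout, cin, k, k))
        elif init == "zero":
            w = np.zeros((cout, cin, k, k))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params = {"w": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}

    def forward(self, x):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.params["w"].reshape(self.cout, -1)
        y = cols @ wmat.T + self.params["b"]
        self._cache = (cols, x.shape, ho, wo)
        n = x.shape[0]
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, ho, wo = self._cache
        n = xshape[0]
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.grads = {
            "w": (dym.T @ cols).reshape(self.params["w"].shape),
            "b": dym.sum(axis=0),
        }
        dcols = dym @ self.params["w"].reshape(self.cout, -1)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad, ho, wo)


class ConvTranspose2D(Layer):
    """Transposed convolution (fractional-stride upsampling).

    Output size is (H - 1) * stride - 2 * pad + k.  With kernel 2f, stride
    f, pad f/2 this upsamples exactly by the factor f; initialized to
    bilinear interpolation unless told otherwise.  No bias (following
    common FCN upsampling practice).
    """

    def __init__(self, cin, cout, k, stride, pad, init="bilinear", rng=None, dtype=np.float64):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        if init == "bilinear":
            if cin != cout:
                raise ValueError("bilinear init requires cin == cout")
            w = bilinear_kernel(cin, k, stride)
        elif init == "he":
            assert rng is not None
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), (cin, cout, k, k))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params = {"w": w.astype(dtype)}

    def out_size(self, h):
        return (h - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x):
        n, cin, h, w = x.shape
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, cin)
        cols = xm @ self.params["w"].reshape(cin, -1)
        out_shape = (n, self.cout, self.out_size(h), self.out_size(w))
        y = _col2im(cols, out_shape, self.k, self.stride, self.pad, h, w)
        self._cache = (xm, x.shape)
        return y

    def backward(self, dy):
        xm, xshape = self._cache
        n, cin, h, w = xshape
        cols_dy, ho, wo = _im2col(dy, self.k, self.stride, self.pad)
        assert (ho, wo) == (h, w)
        self.grads = {"w": (xm.T @ cols_dy).reshape(self.params["w"].shape)}
        dxm = cols_dy @ self.params["w"].reshape(cin, -1).T
        return dxm.reshape(n, h, w, cin).transpose(0, 3, 1, 2)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties route gradient to the first max."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._xshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray, mode: str = "normalized"):
    """Pixelwise softmax cross-entropy over class axis 1.

    ``normalized`` averages over every pixel in the batch; ``unnormalized``
    sums over all pixels (the historical FCN/Caffe convention, which is why
    it demands minuscule learning rates).  Returns (loss, dlogits).
    """
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sm = ez / ez.sum(axis=1, keepdims=True)
    onehot_p = np.take_along_axis(sm, labels[:, None, :, :], axis=1)[:, 0]
    eps = np.finfo(logits.dtype).tiny
    nll = -np.log(np.maximum(onehot_p, eps))
    dsm = sm.copy()
    np.put_along_axis(dsm, labels[:, None, :, :], onehot_p[:, None] - 1.0, axis=1)
    # note: put_along_axis wrote p-1 at the true class; other classes keep p
    if mode == "normalized":
        scale = 1.0 / (n * h * w)
    elif mode == "unnormalized":
        scale = 1.0
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    return float(nll.sum() * scale), dsm * scale


class SGD:
    """Stochastic gradient descent with classical momentum and L2 decay.

    Optional global gradient-norm clipping (across all parameters jointly)
    guards the early epochs, when the loss surface of a freshly initialized
    segmentation net is steep enough to fling plain SGD into divergence.
    """

    def __init__(self, layers, lr, momentum=0.9, weight_decay=0.0, max_grad_norm=None):
        self.layers = [l for l in layers if l.params]
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.max_grad_norm = max_grad_norm
        self.vel = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self):
        scale = 1.0
        if self.max_grad_norm is not None:
            sq = 0.0
            for layer in self.layers:
                for g in layer.grads.values():
                    sq += float((g.astype(np.float64) ** 2).sum())
            norm = np.sqrt(sq)
            if norm > self.max_grad_norm:
                scale = self.max_grad_norm / norm
        for layer, vel in zip(self.layers, self.vel):
            for k, p in layer.params.items():
                g = scale * layer.grads[k] + self.weight_decay * p
                vel[k] = self.momentum * vel[k] - self.lr * g
                p += vel[k]
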