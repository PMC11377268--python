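"""Typed network layers with forward, gradient and relevance machinery.

All feature maps are batch-first: ``(N, H, W, C)`` for spatial layers
(H = frames, W = sensor channels, C = feature maps) and ``(N, F)`` after
flattening. Convolution follows the true-convolution orientation

    C(i, j) = sum_d sum_k x(i - d, j - k) w(d, k)

i.e. cross-correlation with the spatially flipped kernel; since kernels are
learned this is observationally equivalent to cross-correlation, and the
convention is pinned by unit tests. Stride-1 convolutions only; pooling
layers do the downsampling.

The gradient backward passes accept a ``relu_mode`` switch so the same
machinery serves training (``"grad"``), deconvnet (backward ReLU applied to
the incoming signal) and guided backpropagation (both gates).
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Input", "Conv2D", "Dense", "AvgPool", "MaxPool", "Flatten",
    "Concat", "BatchNorm", "Dropout", "Softmax",
    "conv2d_forward", "conv_input_grad", "conv_weight_grad",
]


# ---------------------------------------------------------------------------
# convolution primitives

def _pad_hw(kh: int, kw: int) -> Tuple[int, int, int, int]:
    """'same' zero padding (top, bottom, left, right) for stride 1."""
    return (kh - 1) // 2, kh // 2, (kw - 1) // 2, kw // 2


def _corr2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of (N,H,W,Ci) with (kh,kw,Ci,Co)."""
    kh, kw = w.shape[:2]
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N,OH,OW,Ci,kh,kw)
    wp = w.transpose(2, 0, 1, 3)  # (Ci,kh,kw,Co)
    return np.tensordot(v, wp, axes=([3, 4, 5], [0, 1, 2]))


def _pad_input(x: np.ndarray, kh: int, kw: int, padding: str) -> np.ndarray:
    if padding == "valid":
        return x
    pt, pb, pl, pr = _pad_hw(kh, kw)
    return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))


def conv2d_forward(x: np.ndarray, w: np.ndarray, padding: str = "same") -> np.ndarray:
    """True 2-D convolution of a batch with a (kh,kw,Ci,Co) kernel."""
    wf = w[::-1, ::-1]
    return _corr2d(_pad_input(x, w.shape[0], w.shape[1], padding), wf)


def conv_input_grad(
    dy: np.ndarray, w: np.ndarray, padding: str, in_hw: Tuple[int, int]
) -> np.ndarray:
    """Adjoint of ``conv2d_forward`` with respect to the input."""
    kh, kw = w.shape[:2]
    dyp = np.pad(dy, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
    # correlate with the channel-swapped, spatially unflipped kernel
    dxp = _corr2d(dyp, w.transpose(0, 1, 3, 2))
    if padding == "valid":
        return dxp
    pt, _, pl, _ = _pad_hw(kh, kw)
    H, W = in_hw
    return dxp[:, pt : pt + H, pl : pl + W]


def conv_weight_grad(
    x: np.ndarray, dy: np.ndarray, kernel_hw: Tuple[int, int], padding: str
) -> np.ndarray:
    """Adjoint of ``conv2d_forward`` with respect to the kernel."""
    kh, kw = kernel_hw
    xp = _pad_input(x, kh, kw, padding)
    oh, ow = dy.shape[1], dy.shape[2]
    v = sliding_window_view(xp, (oh, ow), axis=(1, 2))  # (N,kh,kw,Ci,OH,OW)
    dwf = np.tensordot(v, dy, axes=([0, 4, 5], [0, 1, 2]))  # (kh,kw,Ci,Co)
    return dwf[::-1, ::-1]


def _relu_backward(dout: np.ndarray, z: np.ndarray, relu_mode: str) -> np.ndarray:
    if relu_mode == "grad":
        return dout * (z > 0)
    if relu_mode == "deconvnet":
        return np.maximum(dout, 0.0)
    if relu_mode == "guided":
        return np.maximum(dout, 0.0) * (z > 0)
    raise ValueError(f"unknown relu_mode {relu_mode!r}")


# ---------------------------------------------------------------------------
# layers

class Layer:
    """Base layer: stateful forward cache, stateless parameters dict."""

    kind = "base"
    #: does this layer count toward the "stacked layers" tally
    stacked = False

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}
        self.in_shape: Optional[Tuple] = None
        self.out_shape: Optional[Tuple] = None

    # shape propagation (shapes exclude the batch axis)
    def infer_shape(self, in_shapes: List[Tuple]) -> Tuple:
        raise NotImplementedError

    def init_params(self, rng: np.random.Generator) -> None:
        pass

    def forward(self, inputs: List[np.ndarray], mode: str = "eval",
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, relu_mode: str = "grad") -> List[np.ndarray]:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Input(Layer):
    kind = "input"

    def __init__(self, shape: Tuple) -> None:
        super().__init__()
        self.out_shape = tuple(shape)

    def infer_shape(self, in_shapes):
        return self.out_shape

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        if x.shape[1:] != self.out_shape:
            raise ValueError(f"input shape {x.shape[1:]} != expected {self.out_shape}")
        return x

    def backward(self, dout, relu_mode="grad"):
        return [dout]


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2D(Layer):
    kind = "conv2d"
    stacked = True

    def __init__(self, n_filters: int, kernel: Tuple[int, int] = (3, 3),
                 stride: int = 1, padding: str = "same", activation: str = "relu") -> None:
        super().__init__()
        if stride != 1:
            raise ValueError("only stride-1 convolutions are supported")
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.n_filters = n_filters
        self.kernel = tuple(kernel)
        self.padding = padding
        self.activation = activation

    def infer_shape(self, in_shapes):
        (s,) = in_shapes
        h, w, c = s
        kh, kw = self.kernel
        if self.padding == "same":
            oh, ow = h, w
        else:
            oh, ow = h - kh + 1, w - kw + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"kernel {self.kernel} does not fit input {s}")
        self.in_shape = s
        self.out_shape = (oh, ow, self.n_filters)
        return self.out_shape

    def init_params(self, rng):
        kh, kw = self.kernel
        cin = self.in_shape[2]
        fan_in, fan_out = kh * kw * cin, kh * kw * self.n_filters
        self.params["w"] = _glorot(rng, (kh, kw, cin, self.n_filters), fan_in, fan_out)
        self.params["b"] = np.zeros(self.n_filters)

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        self._x = x
        z = conv2d_forward(x, self.params["w"], self.padding) + self.params["b"]
        self._z = z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dout, relu_mode="grad"):
        dz = _relu_backward(dout, self._z, relu_mode) if self.activation == "relu" else dout
        self.grads["w"] = conv_weight_grad(self._x, dz, self.kernel, self.padding)
        self.grads["b"] = dz.sum(axis=(0, 1, 2))
        dx = conv_input_grad(dz, self.params["w"], self.padding, self.in_shape[:2])
        return [dx]


class Dense(Layer):
    kind = "dense"
    stacked = True

    def __init__(self, width: int, activation: str = "relu") -> None:
        super().__init__()
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.width = width
        self.activation = activation

    def infer_shape(self, in_shapes):
        (s,) = in_shapes
        if len(s) != 1:
            raise ValueError("Dense expects flattened input")
        self.in_shape = s
        self.out_shape = (self.width,)
        return self.out_shape

    def init_params(self, rng):
        fin = self.in_shape[0]
        self.params["w"] = _glorot(rng, (fin, self.width), fin, self.width)
        self.params["b"] = np.zeros(self.width)

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        self._x = x
        z = x @ self.params["w"] + self.params["b"]
        self._z = z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dout, relu_mode="grad"):
        dz = _relu_backward(dout, self._z, relu_mode) if self.activation == "relu" else dout
        self.grads["w"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return [dz @ self.params["w"].T]


class _Pool(Layer):
    def __init__(self, window: Tuple[int, int] = (2, 2)) -> None:
        super().__init__()
        self.window = tuple(window)

    def infer_shape(self, in_shapes):
        (s,) = in_shapes
        h, w, c = s
        ph, pw = self.window
        oh, ow = h // ph, w // pw
        if oh < 1 or ow < 1:
            raise ValueError(f"pool window {self.window} too large for input {s}")
        self.in_shape = s
        self.out_shape = (oh, ow, c)
        return self.out_shape

    def _windows(self, x: np.ndarray) -> np.ndarray:
        ph, pw = self.window
        oh, ow, c = self.out_shape
        x2 = x[:, : oh * ph, : ow * pw]
        return x2.reshape(x.shape[0], oh, ph, ow, pw, c)


class AvgPool(_Pool):
    kind = "avgpool"
    stacked = True

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        self._x = x
        return self._windows(x).mean(axis=(2, 4))

    def backward(self, dout, relu_mode="grad"):
        ph, pw = self.window
        oh, ow, c = self.out_shape
        n = dout.shape[0]
        dx = np.zeros((n,) + self.in_shape)
        spread = np.broadcast_to(
            dout[:, :, None, :, None, :] / (ph * pw), (n, oh, ph, ow, pw, c)
        )
        dx[:, : oh * ph, : ow * pw] = spread.reshape(n, oh * ph, ow * pw, c)
        return [dx]


class MaxPool(_Pool):
    kind = "maxpool"
    stacked = True

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        self._x = x
        w = self._windows(x)  # (N,oh,ph,ow,pw,C)
        n, oh, ph, ow, pw, c = w.shape
        flat = w.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, ph * pw, c)
        # ties break to the first (lowest) index within the window
        self._argmax = flat.argmax(axis=3)
        return np.take_along_axis(flat, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout, relu_mode="grad"):
        ph, pw = self.window
        oh, ow, c = self.out_shape
        n = dout.shape[0]
        flat = np.zeros((n, oh, ow, ph * pw, c))
        np.put_along_axis(flat, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros((n,) + self.in_shape)
        block = flat.reshape(n, oh, ow, ph, pw, c).transpose(0, 1, 3, 2, 4, 5)
        dx[:, : oh * ph, : ow * pw] = block.reshape(n, oh * ph, ow * pw, c)
        return [dx]


class Flatten(Layer):
    kind = "flatten"

    def infer_shape(self, in_shapes):
        (s,) = in_shapes
        self.in_shape = s
        self.out_shape = (int(np.prod(s)),)
        return self.out_shape

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, relu_mode="grad"):
        return [dout.reshape((-1,) + self.in_shape)]


class Concat(Layer):
    kind = "concat"

    def infer_shape(self, in_shapes):
        if len(in_shapes) < 2:
            raise ValueError("concat needs >= 2 parents")
        base = in_shapes[0][:-1]
        for s in in_shapes[1:]:
            if s[:-1] != base:
                raise ValueError(f"concat shapes incompatible: {in_shapes}")
        self.part_channels = [s[-1] for s in in_shapes]
        self.in_shape = in_shapes
        self.out_shape = base + (sum(self.part_channels),)
        return self.out_shape

    def forward(self, inputs, mode="eval", rng=None):
        return np.concatenate(inputs, axis=-1)

    def backward(self, dout, relu_mode="grad"):
        return list(np.split(dout, np.cumsum(self.part_channels)[:-1], axis=-1))


class BatchNorm(Layer):
    kind = "batchnorm"

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def infer_shape(self, in_shapes):
        (s,) = in_shapes
        self.in_shape = s
        self.out_shape = s
        return s

    def init_params(self, rng):
        c = self.in_shape[-1]
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def _axes(self, x: np.ndarray) -> Tuple[int, ...]:
        return tuple(range(x.ndim - 1))

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        self._x = x
        if mode == "train":
            axes = self._axes(x)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._mean, self._var = mean, var
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._train_mode = mode == "train"
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout, relu_mode="grad"):
        axes = self._axes(dout)
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        inv_sd = 1.0 / np.sqrt(self._var + self.eps)
        dxhat = dout * self.params["gamma"]
        if not self._train_mode:
            return [dxhat * inv_sd]
        m = np.prod([dout.shape[a] for a in axes])
        dx = (inv_sd / m) * (
            m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )
        return [dx]

    def effective_affine(self) -> Tuple[np.ndarray, np.ndarray]:
        """Inference-mode per-channel (scale, shift): y = scale*x + shift."""
        inv_sd = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.params["gamma"] * inv_sd
        shift = self.params["beta"] - self.running_mean * scale
        return scale, shift


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, rate: float = 0.3) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def infer_shape(self, in_shapes):
        (s,) = in_shapes
        self.in_shape = s
        self.out_shape = s
        return s

    def forward(self, inputs, mode="eval", rng=None):
        (x,) = inputs
        if mode != "train" or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout, relu_mode="grad"):
        if self._mask is None:
            return [dout]
        return [dout * self._mask]


class Softmax(Layer):
    kind = "softmax"

    def infer_shape(self, in_shapes):
        (s,) = in_shapes
        self.in_shape = s
        self.out_shape = s
        return s

    def forward(self, inputs, mode="eval", rng=None):
        (z,) = inputs
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dout, relu_mode="grad"):
        p = self._p
        return [p * (dout - (dout * p).sum(axis=-1, keepdims=True))]
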