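"""Layers with explicit forward/backward passes.

Activations are float32 arrays in (batch, channels, height, width) layout for
the convolutional stack and (batch, features) after flattening.  Convolution
uses "same" zero padding (pad = k // 2 for odd k) so spatial size only drops
via stride and pooling; backward for a strided convolution never propagates
an input gradient (the strided layer is always first in this architecture).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2D", "MeanPool2D", "MaxPool2D", "ELU", "Flatten", "Dense"]


class Layer:
    name: str = "layer"

    #: parameter arrays, mutated in place by the optimizer
    params: list
    #: gradient arrays aligned with ``params``; overwritten by backward()
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def output_shape(self, in_shape: tuple) -> tuple:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B*Ho*Wo, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (B, C, Hf, Wf, k, k)
    win = win[:, :, ::stride, :: stride]
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2D(Layer):
    """2-D correlation with "same" zero padding.

    weight: (out_channels, in_channels, k, k); bias: (out_channels,).
    """

    def __init__(
        self, in_channels: int, out_channels: int, kernel: int, stride: int = 1,
        name: str = "conv", needs_input_grad: bool = True,
    ) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel
        self.stride = stride
        self.pad = kernel // 2
        self.name = name
        self.needs_input_grad = needs_input_grad
        self.weight = np.zeros((out_channels, in_channels, kernel, kernel), np.float32)
        self.bias = np.zeros(out_channels, np.float32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    @property
    def fan_in(self) -> int:
        """Spatial window x feature inputs per unit."""
        return self.k * self.k * self.cin

    def output_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        if c != self.cin:
            raise ValueError(
                f"{self.name}: expected {self.cin} input channels, got {c}"
            )
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        return (self.cout, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        _, ho, wo = self.output_shape(x.shape[1:])
        cols = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.weight.reshape(self.cout, -1)
        y = cols @ wmat.T + self.bias
        self._cols = cols
        self._in_shape = x.shape
        return y.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, ho, wo = dy.shape
        dyc = dy.transpose(0, 2, 3, 1).reshape(b * ho * wo, self.cout)
        self.grads[0][...] = (dyc.T @ self._cols).reshape(self.weight.shape)
        self.grads[1][...] = dyc.sum(axis=0)
        if not self.needs_input_grad:
            # first-layer convolution: no gradient to the raw image needed
            return None
        if self.stride != 1:
            raise NotImplementedError(
                f"{self.name}: input gradient for strided convolution is not "
                "supported (strided layers sit first in this architecture)"
            )
        # dX = same-padding correlation of dy with spatially flipped,
        # channel-transposed weights (valid because pad == k//2, stride 1)
        wflip = self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,k,k)
        cols_dy = _im2col(dy, self.k, 1, self.pad)
        dx = cols_dy @ wflip.reshape(self.cin, -1).T
        return dx.reshape(b, ho, wo, self.cin).transpose(0, 3, 1, 2)


class MeanPool2D(Layer):
    """2x2 average pooling, stride 2: keeps interpolable position information
    (the architectural choice that favours precise localization over the
    translation invariance of max pooling)."""

    def __init__(self, name: str = "meanpool") -> None:
        super().__init__()
        self.name = name

    def output_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        if h % 2 or w % 2:
            raise ValueError(f"{self.name}: spatial size {(h, w)} not divisible by 2")
        return (c, h // 2, w // 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.repeat(2, axis=2).repeat(2, axis=3) * np.float32(0.25)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2 (the comparator variant).  Gradient is
    split equally among tied maxima within a window."""

    def __init__(self, name: str = "maxpool") -> None:
        super().__init__()
        self.name = name

    def output_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        if h % 2 or w % 2:
            raise ValueError(f"{self.name}: spatial size {(h, w)} not divisible by 2")
        return (c, h // 2, w // 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        counts = self._mask.sum(axis=(3, 5))
        share = (dy / counts)[:, :, :, None, :, None]
        dxr = self._mask * share
        b, c, hh, _, ww, _ = dxr.shape
        return dxr.reshape(b, c, hh * 2, ww * 2).astype(dy.dtype, copy=False)


class ELU(Layer):
    """Exponential linear unit: x for x >= 0, exp(x) - 1 otherwise."""

    def __init__(self, name: str = "elu") -> None:
        super().__init__()
        self.name = name

    def output_shape(self, in_shape: tuple) -> tuple:
        return in_shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.where(x >= 0, x, np.expm1(np.minimum(x, 0))).astype(
            np.float32, copy=False
        )
        self._y = y
        self._neg = x < 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grad = np.where(self._neg, self._y + 1.0, 1.0)
        return (dy * grad).astype(np.float32, copy=False)


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        super().__init__()
        self.name = name

    def output_shape(self, in_shape: tuple) -> tuple:
        return (int(np.prod(in_shape)),)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer: y = x @ W + b; W is (fan_in, fan_out)."""

    def __init__(self, fan_in: int, fan_out: int, name: str = "fc") -> None:
        super().__init__()
        self.name = name
        self.weight = np.zeros((fan_in, fan_out), np.float32)
        self.bias = np.zeros(fan_out, np.float32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    @property
    def fan_in(self) -> int:
        return self.weight.shape[0]

    def output_shape(self, in_shape: tuple) -> tuple:
        if in_shape != (self.weight.shape[0],):
            raise ValueError(
                f"{self.name}: expected input {(self.weight.shape[0],)}, got {in_shape}"
            )
        return (self.weight.shape[1],)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.weight.T
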