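"""Minimal NumPy neural-network layers with explicit backpropagation.

Only the operations the reconstruction networks need are provided: 3D
convolution ("same" padding), anisotropic in-plane max-pooling and nearest
upsampling with kernel (1, 2, 2), dense layers for the coordinate MLP,
ReLU, and channel softmax.  Every layer caches what its backward pass needs;
``backward`` consumes the upstream gradient and accumulates parameter
gradients in-place.

Tensors are channel-first: volumes are ``(C, D, H, W)``, point batches are
``(N, F)``.  Float32 is the working precision; float64 is supported so the
test suite can run numeric gradient checks at tight tolerance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "ReLU",
    "MaxPoolInPlane",
    "UpsampleInPlane",
    "Linear",
    "Sequential",
    "softmax_channels",
    "softmax_backward",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: stateless unless it owns Parameters."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Layer):
    """3D convolution with odd kernel and zero "same" padding.

    Implemented as a sum of shifted channel-mixing GEMMs (one per kernel
    tap), which keeps peak memory at one padded copy of the input instead of
    a full im2col matrix.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "conv"):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("Conv3d requires odd kernel sizes")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * int(np.prod(kernel))
        self.weight = Parameter(
            _he_init(rng, (out_channels, in_channels) + kernel, fan_in, dtype),
            name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype),
                              name=f"{name}.bias")
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[0]}")
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
        self._xp = xp
        _, D, H, W = x.shape
        out = np.zeros((self.out_channels, D, H, W), dtype=x.dtype)
        w = self.weight.value
        # one GEMM per tap on the contiguous padded canvas, accumulated
        # through shifted views — avoids per-tap input copies
        xf = xp.reshape(self.in_channels, -1)
        full_shape = (self.out_channels,) + xp.shape[1:]
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    y = (w[:, :, i, j, k] @ xf).reshape(full_shape)
                    out += y[:, i:i + D, j:j + H, k:k + W]
        out += self.bias.value[:, None, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called before forward")
        kd, kh, kw = self.kernel
        _, D, H, W = grad.shape
        w = self.weight.value
        grad = np.ascontiguousarray(grad)
        gf = grad.reshape(self.out_channels, -1)
        dxp = np.zeros_like(xp)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    sl = xp[:, i:i + D, j:j + H, k:k + W]
                    self.weight.grad[:, :, i, j, k] += np.tensordot(
                        grad, sl, axes=([1, 2, 3], [1, 2, 3]))
                    g = (w[:, :, i, j, k].T @ gf).reshape(
                        (self.in_channels, D, H, W))
                    dxp[:, i:i + D, j:j + H, k:k + W] += g
        self.bias.grad += grad.sum(axis=(1, 2, 3))
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        return dxp[:, pd:pd + D, ph:ph + H, pw:pw + W]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPoolInPlane(Layer):
    """(1, 2, 2) max pooling: halves H and W, preserves depth."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, D, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("in-plane dims must be even for (1,2,2) pooling")
        v = x.reshape(C, D, H // 2, 2, W // 2, 2)
        v = v.transpose(0, 1, 2, 4, 3, 5).reshape(C, D, H // 2, W // 2, 4)
        self._idx = v.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        C, D, H, W = self._in_shape
        flat = np.zeros((C, D, H // 2, W // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(C, D, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(C, D, H, W)


class UpsampleInPlane(Layer):
    """(1, 2, 2) nearest-neighbour upsampling: doubles H and W."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        C, D, H2, W2 = grad.shape
        v = grad.reshape(C, D, H2 // 2, 2, W2 // 2, 2)
        return v.sum(axis=(3, 5))


class InstanceNorm(Layer):
    """Per-channel normalization over the spatial axes of a (C, D, H, W)
    tensor, with learnable scale and shift.

    The batch-size here is one volume, so this is the appropriate
    normalization; it keeps activations (and hence logits) bounded, which
    prevents softmax saturation under heavily class-imbalanced targets.
    """

    def __init__(self, channels: int, eps: float = 1e-5,
                 dtype=np.float32, name: str = "inorm"):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype),
                               name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype),
                              name=f"{name}.beta")

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (1, 2, 3)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._n = int(np.prod(x.shape[1:]))
        g = self.gamma.value[:, None, None, None]
        b = self.beta.value[:, None, None, None]
        return g * self._xhat + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (1, 2, 3)
        xhat, std, n = self._xhat, self._std, self._n
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value[:, None, None, None]
        # standard normalization backward over the spatial axes
        return (dxhat - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) / std


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "linear"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(
            _he_init(rng, (in_features, out_features), in_features, dtype),
            name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_features, dtype=dtype),
                              name=f"{name}.bias")

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 0 (the channel axis) of a (C, ...) tensor."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Gradient through ``softmax_channels`` given dL/dP."""
    dot = (dprobs * probs).sum(axis=0, keepdims=True)
    return probs * (dprobs - dot)
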