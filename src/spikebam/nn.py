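"""Minimal NumPy layer library with hand-written backpropagation.

Batched 1-D signals are laid out ``(batch, channels, length)`` throughout.
Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad``; ``backward`` returns the
gradient with respect to the layer input.  Gradient correctness is enforced
by finite-difference tests rather than an autograd engine.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He/Kaiming fan-in-scaled uniform init (variance ~2/fan_in).

    Keeps activation variance roughly constant through stacked ReLU convs,
    which matters here: the LIF population only passes gradient where the
    membrane potential lands inside the rectangular surrogate window, so
    under-scaled init silences the whole latent code.
    """
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1dSame(Layer):
    """Length-preserving 1-D convolution (odd kernel, zero padding k//2)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for length-preserving conv")
        fan = c_in * kernel
        self.w = Param(_fan_in_uniform(rng, (c_out, c_in, kernel), fan))
        self.b = Param(_fan_in_uniform(rng, (c_out,), fan))
        self.kernel = kernel
        self.pad = kernel // 2

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, _, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp, self._len = xp, length
        y = np.zeros((x.shape[0], self.w.value.shape[0], length))
        for j in range(self.kernel):
            y += np.einsum(
                "oc,bcl->bol", self.w.value[:, :, j], xp[:, :, j : j + length], optimize=True
            )
        return y + self.b.value[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, length = self._xp, self._len
        gxp = np.zeros_like(xp)
        for j in range(self.kernel):
            self.w.grad[:, :, j] += np.einsum(
                "bol,bcl->oc", gy, xp[:, :, j : j + length], optimize=True
            )
            gxp[:, :, j : j + length] += np.einsum(
                "oc,bol->bcl", self.w.value[:, :, j], gy, optimize=True
            )
        self.b.grad += gy.sum(axis=(0, 2))
        return gxp[:, :, self.pad : self.pad + length]


class ConvTranspose1d(Layer):
    """Strided transposed 1-D convolution for upsampling.

    With kernel 8, stride 2, padding 3 the output length is exactly twice
    the input length: ``(L-1)*stride - 2*padding + kernel = 2L``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
    ):
        fan = c_in * kernel // stride
        self.w = Param(_fan_in_uniform(rng, (c_in, c_out, kernel), max(fan, 1)))
        self.b = Param(_fan_in_uniform(rng, (c_out,), max(fan, 1)))
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_len(self, length: int) -> int:
        return (length - 1) * self.stride - 2 * self.padding + self.kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        batch, _, length = x.shape
        self._x = x
        c_out = self.w.value.shape[1]
        full = np.zeros((batch, c_out, (length - 1) * self.stride + self.kernel))
        for j in range(self.kernel):
            full[:, :, j : j + (length - 1) * self.stride + 1 : self.stride] += np.einsum(
                "co,bcl->bol", self.w.value[:, :, j], x, optimize=True
            )
        y = full[:, :, self.padding : self.padding + self.out_len(length)]
        return y + self.b.value[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        batch, _, length = x.shape
        gfull = np.zeros((batch, gy.shape[1], (length - 1) * self.stride + self.kernel))
        gfull[:, :, self.padding : self.padding + self.out_len(length)] = gy
        gx = np.zeros_like(x)
        for j in range(self.kernel):
            sl = gfull[:, :, j : j + (length - 1) * self.stride + 1 : self.stride]
            self.w.grad[:, :, j] += np.einsum("bcl,bol->co", x, sl, optimize=True)
            gx += np.einsum("co,bol->bcl", self.w.value[:, :, j], sl, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        return gx


class AvgPool1d(Layer):
    def __init__(self, size: int = 2, stride: int = 2):
        if size != stride:
            raise ValueError("only non-overlapping pooling supported")
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        if length % self.size:
            raise ValueError(f"length {length} not divisible by pool size {self.size}")
        return x.reshape(b, c, length // self.size, self.size).mean(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy, self.size, axis=2) / self.size


class MaxPool1d(Layer):
    def __init__(self, size: int = 2, stride: int = 2):
        if size != stride:
            raise ValueError("only non-overlapping pooling supported")
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        if length % self.size:
            raise ValueError(f"length {length} not divisible by pool size {self.size}")
        xr = x.reshape(b, c, length // self.size, self.size)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, lo = gy.shape
        gx = np.zeros((b, c, lo, self.size))
        np.put_along_axis(gx, self._arg[..., None], gy[..., None], axis=3)
        return gx.reshape(b, c, lo * self.size)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class PointwiseLinear(Layer):
    """Fully connected layer applied independently at every time step.

    Maps ``(B, c_in, L)`` to ``(B, c_out, L)`` with a shared ``(c_out, c_in)``
    weight — how the encoder features feed the LIF population and the spikes
    feed the decoder.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = Param(_fan_in_uniform(rng, (c_out, c_in), c_in))
        self.b = Param(_fan_in_uniform(rng, (c_out,), c_in))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,bcl->bol", self.w.value, x, optimize=True) + self.b.value[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("bol,bcl->oc", gy, self._x, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        return np.einsum("oc,bol->bcl", self.w.value, gy, optimize=True)


class Dense(Layer):
    """Plain fully connected layer on flat vectors, ``(B, n_in) -> (B, n_out)``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_fan_in_uniform(rng, (n_out, n_in), n_in))
        self.b = Param(_fan_in_uniform(rng, (n_out,), n_in))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adam optimizer (Kingma & Ba) over a flat parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
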