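"""Layers with hand-derived backward passes.

Tensors are ``(N, C, L)`` — batch, channels, temporal length — except after
pooling, where they are ``(N, C)``. Convolutions are evaluated as a short sum
of strided matrix products over kernel taps (kernels here are at most 7 wide),
which keeps everything inside BLAS without an im2col copy.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "ReLU",
    "Linear",
    "AvgPool1d",
    "Sequential",
    "PreActBottleneck",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: forward caches whatever backward needs."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    """1D convolution (cross-correlation), stride ``s``, symmetric zero padding.

    Output length is ``(L + 2p - k) // s + 1``. MAC cost per sample is
    ``k * C_in * C_out * L_out``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2 if kernel > 1 else 0
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.stride, self.padding = stride, padding
        self.W = Param(_he_init(rng, (out_channels, in_channels, kernel),
                                in_channels * kernel), "W")
        self.b = Param(np.zeros(out_channels), "b") if bias else None
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_length(self, L: int) -> int:
        return (L + 2 * self.padding - self.k) // self.stride + 1

    def macs(self, L_in: int) -> int:
        return self.k * self.cin * self.cout * self.out_length(L_in)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, L = x.shape
        p, s, k = self.padding, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        Lout = self.out_length(L)
        y = np.zeros((N, self.cout, Lout))
        for i in range(k):
            xs = xp[:, :, i : i + s * Lout : s]  # (N, Cin, Lout)
            y += np.einsum("oc,ncl->nol", self.W.data[:, :, i], xs, optimize=True)
        if self.b is not None:
            y += self.b.data[None, :, None]
        self._cache = (xp, x.shape, Lout)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, xshape, Lout = self._cache
        p, s, k = self.padding, self.stride, self.k
        gxp = np.zeros_like(xp)
        for i in range(k):
            xs = xp[:, :, i : i + s * Lout : s]
            self.W.grad[:, :, i] += np.einsum("nol,ncl->oc", gy, xs, optimize=True)
            gxp[:, :, i : i + s * Lout : s] += np.einsum(
                "oc,nol->ncl", self.W.data[:, :, i], gy, optimize=True
            )
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2))
        return gxp[:, :, p : p + xshape[2]] if p else gxp


class ConvTranspose1d(Module):
    """Transposed 1D convolution (fractionally strided upsampling).

    Output length is ``(L - 1) * s - 2p + k + output_padding``; the adjoint of
    :class:`Conv1d` with the same geometry. Weight layout is
    ``(C_in, C_out, k)``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, output_padding: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        self.W = Param(_he_init(rng, (in_channels, out_channels, kernel),
                                in_channels * kernel), "W")
        self.b = Param(np.zeros(out_channels), "b") if bias else None
        self._cache: tuple | None = None

    @staticmethod
    def geometry_for(L_in: int, L_out: int, kernel: int, stride: int) -> tuple[int, int]:
        """Solve (padding, output_padding) so L_in maps exactly to L_out."""
        base = (L_in - 1) * stride + kernel
        for padding in range(kernel):
            op = L_out - base + 2 * padding
            if 0 <= op < stride or (0 <= op and stride == 1 and op == 0):
                return padding, op
        raise ValueError(
            f"no transposed-conv geometry maps {L_in} -> {L_out} with k={kernel}, s={stride}"
        )

    def parameters(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_length(self, L: int) -> int:
        return (L - 1) * self.stride - 2 * self.padding + self.k + self.output_padding

    def macs(self, L_in: int) -> int:
        # one MAC per kernel tap per input position per channel pair
        return self.k * self.cin * self.cout * L_in

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, L = x.shape
        s, p, k = self.stride, self.padding, self.k
        Lfull = (L - 1) * s + k
        Lout = self.out_length(L)
        yfull = np.zeros((N, self.cout, max(Lfull, p + Lout)))
        for i in range(k):
            yfull[:, :, i : i + s * L : s] += np.einsum(
                "co,ncl->nol", self.W.data[:, :, i], x, optimize=True
            )
        y = yfull[:, :, p : p + Lout].copy()
        if self.b is not None:
            y += self.b.data[None, :, None]
        self._cache = (x, Lfull)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, Lfull = self._cache
        N, C, L = x.shape
        s, p, k = self.stride, self.padding, self.k
        Lout = gy.shape[2]
        gyfull = np.zeros((N, self.cout, max(Lfull, p + Lout)))
        gyfull[:, :, p : p + Lout] = gy
        gx = np.zeros_like(x)
        for i in range(k):
            gys = gyfull[:, :, i : i + s * L : s]
            self.W.grad[:, :, i] += np.einsum("ncl,nol->co", x, gys, optimize=True)
            gx += np.einsum("co,nol->ncl", self.W.data[:, :, i], gys, optimize=True)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2))
        return gx


class BatchNorm1d(Module):
    """Per-channel batch normalization over the batch and temporal axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels), "gamma")
        self.beta = Param(np.zeros(channels), "beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        self.beta.grad += gy.sum(axis=(0, 2))
        g = self.gamma.data[None, :, None] * gy
        if not train:
            return g * inv_std[None, :, None]
        m = xhat.shape[0] * xhat.shape[2]
        gsum = g.sum(axis=(0, 2), keepdims=True)
        gxhat_sum = (g * xhat).sum(axis=(0, 2), keepdims=True)
        return inv_std[None, :, None] * (g - gsum / m - xhat * gxhat_sum / m)


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class Linear(Module):
    """Fully connected layer on ``(N, F)`` inputs."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.fin, self.fout = in_features, out_features
        self.W = Param(_he_init(rng, (out_features, in_features), in_features), "W")
        self.b = Param(np.zeros(out_features), "b") if bias else None
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def macs(self) -> int:
        return self.fin * self.fout

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        y = x @ self.W.data.T
        if self.b is not None:
            y += self.b.data
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += gy.T @ self._x
        if self.b is not None:
            self.b.grad += gy.sum(axis=0)
        return gy @ self.W.data


class AvgPool1d(Module):
    """Average pooling over the full temporal extent: (N, C, L) -> (N, C)."""

    def __init__(self) -> None:
        self._L: int | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy[:, :, None], self._L, axis=2) / self._L


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def parameters(self) -> list[Param]:
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            gy = m.backward(gy)
        return gy


class PreActBottleneck(Module):
    """Pre-activation bottleneck residual unit.

    Three convolutions (1x1 reduce, kx1 transform, 1x1 expand), each preceded
    by BN and ReLU. The shortcut is the identity when shapes are unchanged;
    otherwise a learned 1x1 (transposed) projection with matching stride,
    applied to the first pre-activation output, as in standard pre-activation
    residual networks. The optional stride or upsampling sits on the *first*
    convolution.
    """

    def __init__(self, in_channels: int, c1: int, c2: int, c3: int,
                 kernel: int = 3, stride: int = 1, transposed: bool = False,
                 output_padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, c3
        self.stride, self.transposed = stride, transposed
        self.bn1 = BatchNorm1d(in_channels)
        self.relu1 = ReLU()
        if transposed:
            self.conv1: Module = ConvTranspose1d(
                in_channels, c1, 1, stride=stride, padding=0,
                output_padding=output_padding, bias=bias, rng=rng)
        else:
            self.conv1 = Conv1d(in_channels, c1, 1, stride=stride, bias=bias, rng=rng)
        self.bn2 = BatchNorm1d(c1)
        self.relu2 = ReLU()
        self.conv2 = Conv1d(c1, c2, kernel, stride=1, bias=bias, rng=rng)
        self.bn3 = BatchNorm1d(c2)
        self.relu3 = ReLU()
        self.conv3 = Conv1d(c2, c3, 1, stride=1, bias=bias, rng=rng)
        self.needs_projection = (in_channels != c3) or (stride != 1)
        if self.needs_projection:
            if transposed:
                self.proj: Module | None = ConvTranspose1d(
                    in_channels, c3, 1, stride=stride, padding=0,
                    output_padding=output_padding, bias=bias, rng=rng)
            else:
                self.proj = Conv1d(in_channels, c3, 1, stride=stride, bias=bias, rng=rng)
        else:
            self.proj = None

    def parameters(self) -> list[Param]:
        mods = [self.bn1, self.conv1, self.bn2, self.conv2, self.bn3, self.conv3]
        if self.proj is not None:
            mods.append(self.proj)
        return [p for m in mods for p in m.parameters()]

    def main_path_convs(self) -> list[Module]:
        return [self.conv1, self.conv2, self.conv3]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a = self.relu1.forward(self.bn1.forward(x, train), train)
        h = self.conv1.forward(a, train)
        h = self.conv2.forward(self.relu2.forward(self.bn2.forward(h, train), train), train)
        h = self.conv3.forward(self.relu3.forward(self.bn3.forward(h, train), train), train)
        shortcut = x if self.proj is None else self.proj.forward(a, train)
        return h + shortcut

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gh = self.conv3.backward(gy)
        gh = self.bn3.backward(self.relu3.backward(gh))
        gh = self.conv2.backward(gh)
        gh = self.bn2.backward(self.relu2.backward(gh))
        ga = self.conv1.backward(gh)
        if self.proj is None:
            gx_short, ga_short = gy, None
        else:
            gx_short, ga_short = None, self.proj.backward(gy)
        if ga_short is not None:
            ga = ga + ga_short
        gx = self.bn1.backward(self.relu1.backward(ga))
        if gx_short is not None:
            gx = gx + gx_short
        return gx
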