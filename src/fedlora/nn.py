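"""Minimal numpy neural-network layers with explicit forward/backward passes.

Only what an EfficientNet-style backbone needs: dense and depthwise 2-D
convolutions (with an optional low-rank adapter branch on group-1
convolutions), frozen batch normalization, SiLU, squeeze-and-excite,
global average pooling, dropout and an affine classifier.  Tensors are
NCHW ``float32``.  Backward passes propagate an input gradient through
every layer (so adapters deep in the network receive gradients) but only
accumulate parameter gradients on unfrozen parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float32


class Parameter:
    """An array with a gradient slot and a freeze flag."""

    __slots__ = ("data", "grad", "frozen", "name")

    def __init__(self, data: np.ndarray, frozen: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.frozen = frozen
        self.name = name

    @property
    def size(self) -> int:
        return int(self.data.size)

    def zero_grad(self) -> None:
        self.grad = None

    def add_grad(self, g: np.ndarray) -> None:
        if self.frozen:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g.astype(DTYPE, copy=False)


class Module:
    """Base layer: named parameters, train/eval mode, forward/backward."""

    def __init__(self) -> None:
        self.training = False

    # -- parameter traversal ------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            if isinstance(val, Parameter):
                yield (prefix + key if not prefix else f"{prefix}.{key}"), val
            elif isinstance(val, Module):
                sub = key if not prefix else f"{prefix}.{key}"
                yield from val.named_parameters(sub)
            elif isinstance(val, list):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        sub = f"{key}.{i}" if not prefix else f"{prefix}.{key}.{i}"
                        yield from item.named_parameters(sub)

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for key, val in vars(self).items():
            if isinstance(val, Module):
                sub = key if not prefix else f"{prefix}.{key}"
                yield from val.named_modules(sub)
            elif isinstance(val, list):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        sub = f"{key}.{i}" if not prefix else f"{prefix}.{key}.{i}"
                        yield from item.named_modules(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def freeze(self, frozen: bool = True) -> None:
        for p in self.parameters():
            p.frozen = frozen

    # -- computation --------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Extract sliding patches: (N,C,H,W) -> (N, C, kh*kw, Ho*Wo)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
    )
    cols = np.ascontiguousarray(view).reshape(n, c, kh * kw, ho * wo)
    return cols, ho, wo


def col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add patch gradients back to the input, inverse of im2col."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    d = dcols.reshape(n, c, kh, kw, ho, wo)
    dx = np.zeros((n, c, hp, wp), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """2-D convolution, groups=1 or depthwise (groups == in_channels == out_channels).

    Padding is ``kernel // 2`` so stride-1 convolutions preserve the spatial
    size and stride-2 convolutions halve it (ceil division on even sizes).
    A group-1 convolution may carry a low-rank adapter (set by
    :func:`fedlora.lora.inject_lora`); the adapter branch adds
    ``scaling * A @ (B @ dropout(patches))`` to the frozen output.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 groups: int = 1, bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        if groups not in (1, in_ch) or (groups == in_ch and out_ch != in_ch and groups != 1):
            raise ValueError("only dense (groups=1) or depthwise convolutions are supported")
        self.in_ch, self.out_ch, self.kernel, self.stride, self.groups = in_ch, out_ch, kernel, stride, groups
        self.pad = kernel // 2
        fan = (in_ch // groups) * kernel * kernel
        rng = rng or np.random.default_rng(0)
        w = _trunc_normal(rng, (out_ch, in_ch // groups, kernel, kernel), std=np.sqrt(2.0 / fan))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.adapter = None  # set by lora.inject_lora
        self._cache = None

    # flattened kernel fans: d = out_ch, k = (in_ch // groups) * kh * kw
    @property
    def fan_out(self) -> int:
        return self.out_ch

    @property
    def fan_in(self) -> int:
        return (self.in_ch // self.groups) * self.kernel * self.kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        n = x.shape[0]
        cols, ho, wo = im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        if self.groups == 1:
            flat = cols.reshape(n, self.fan_in, ho * wo)
            wf = self.weight.data.reshape(self.out_ch, self.fan_in)
            y = np.matmul(wf, flat)
            ad_cache = None
            if self.adapter is not None:
                y2, ad_cache = self.adapter.forward(flat, self.training)
                y = y + y2
            if self.training:
                self._cache = (x.shape, flat, ad_cache)
        else:  # depthwise: cols (N,C,kk,L), w (C,1,kh,kw)
            wf = self.weight.data.reshape(self.out_ch, self.fan_in)
            y = np.einsum("nckl,ck->ncl", cols, wf, optimize=True)
            if self.training:
                self._cache = (x.shape, cols, None)
        if self.bias is not None:
            y = y + self.bias.data[None, :, None]
        return np.ascontiguousarray(y.reshape(n, self.out_ch, ho, wo), dtype=DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, cols, ad_cache = self._cache
        self._cache = None
        n = dy.shape[0]
        dyf = dy.reshape(n, self.out_ch, -1)
        if self.bias is not None:
            self.bias.add_grad(dyf.sum(axis=(0, 2)))
        if self.groups == 1:
            wf = self.weight.data.reshape(self.out_ch, self.fan_in)
            if not self.weight.frozen:
                self.weight.add_grad(
                    np.einsum("nol,nkl->ok", dyf, cols, optimize=True).reshape(self.weight.data.shape)
                )
            dcols = np.matmul(wf.T, dyf)
            if self.adapter is not None:
                dcols += self.adapter.backward(dyf, ad_cache)
        else:
            wf = self.weight.data.reshape(self.out_ch, self.fan_in)
            if not self.weight.frozen:
                self.weight.add_grad(
                    np.einsum("nol,nokl->ok", dyf, cols.reshape(n, self.out_ch, self.fan_in, -1),
                              optimize=True).reshape(self.weight.data.shape)
                )
            dcols = np.einsum("nol,ok->nokl", dyf, wf, optimize=True)
        # dcols is (N, in_ch*kk, L) dense or (N, C, kk, L) depthwise; both
        # reshape to (N, C, kh, kw, Ho, Wo) inside col2im.
        return col2im(dcols, xshape, self.kernel, self.kernel, self.stride, self.pad)


class BatchNorm2d(Module):
    """Batch normalization used in frozen (inference-statistics) mode.

    Running statistics are buffers initialized to mean 0, variance 1 and are
    never updated during client training; gamma/beta are part of the frozen
    backbone parameter set.
    """

    def __init__(self, ch: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.eps = eps
        self.calibrating = False
        self._cache = None

    def _scale(self) -> np.ndarray:
        return self.gamma.data / np.sqrt(self.running_var + self.eps)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.calibrating:
            self.running_mean = x.mean(axis=(0, 2, 3)).astype(DTYPE)
            self.running_var = x.var(axis=(0, 2, 3)).astype(DTYPE)
        s = self._scale()
        y = x * s[None, :, None, None] + (self.beta.data - self.running_mean * s)[None, :, None, None]
        if self.training:
            self._cache = (x, s)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._cache
        self._cache = None
        if not self.gamma.frozen:
            xhat = (x - self.running_mean[None, :, None, None]) / np.sqrt(
                self.running_var + self.eps)[None, :, None, None]
            self.gamma.add_grad(np.sum(dy * xhat, axis=(0, 2, 3)))
        if not self.beta.frozen:
            self.beta.add_grad(dy.sum(axis=(0, 2, 3)))
        return dy * s[None, :, None, None]


class SiLU(Module):
    """Swish activation x * sigmoid(x)."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        sig = _sigmoid(x)
        if self.training:
            self._cache = (x, sig)
        return x * sig

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, sig = self._cache
        self._cache = None
        return dy * (sig * (1.0 + x * (1.0 - sig)))


class SqueezeExcite(Module):
    """Global squeeze, two 1x1 convolutions (SiLU / sigmoid), channel gate."""

    def __init__(self, ch: int, reduced: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = Conv2d(ch, reduced, 1, bias=True, rng=rng)
        self.act = SiLU()
        self.expand = Conv2d(reduced, ch, 1, bias=True, rng=rng)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        hw = x.shape[2] * x.shape[3]
        s = x.mean(axis=(2, 3), keepdims=True)
        g = _sigmoid(self.expand(self.act(self.reduce(s))))
        if self.training:
            self._cache = (x, g, hw)
        return x * g

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, g, hw = self._cache
        self._cache = None
        dx = dy * g
        dg = np.sum(dy * x, axis=(2, 3), keepdims=True)
        # through sigmoid gate
        dpre = dg * g * (1.0 - g)
        ds = self.reduce.backward(self.act.backward(self.expand.backward(dpre)))
        dx += ds / hw  # broadcast of the mean-pool gradient
        return dx


class GlobalAvgPool(Module):
    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache
        self._cache = None
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)).astype(DTYPE) / (h * w)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws masks from its own rng."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape, dtype=np.float32) >= self.p).astype(DTYPE) / (1.0 - self.p)
        self._cache = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return dy
        mask = self._cache
        self._cache = None
        return dy * mask


class Linear(Module):
    """Affine map used as the (private) classifier head."""

    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_trunc_normal(rng, (out_f, in_f), std=np.sqrt(1.0 / in_f)))
        self.bias = Parameter(np.zeros(out_f))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        if not self.weight.frozen:
            self.weight.add_grad(dy.T @ x)
        if not self.bias.frozen:
            self.bias.add_grad(dy.sum(axis=0))
        return dy @ self.weight.data


# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal draw truncated to two standard deviations (resampled tails)."""
    x = rng.standard_normal(shape) * std
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum())) * std
        bad = np.abs(x) > 2 * std
    return x.astype(DTYPE)
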