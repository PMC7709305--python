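"""A small 3D fully-convolutional encoder-decoder (U-Net style) in pure
numpy, with manual backpropagation.

The network maps a single-channel ROI volume to a voxel-wise foreground
probability map of the same shape.  Architecture: ``depth`` max-pooling
stages; at resolution level i two 3x3x3 convolutions with
``base_filters * 2**i`` channels, each followed by ReLU and (in training
mode) inverted dropout; nearest-neighbour upsampling with skip-connection
concatenation on the way up; a final 1x1x1 convolution plus sigmoid.

Convolutions are evaluated as im2col matrix products
(``sliding_window_view`` + GEMM), which keeps a desk-scale model fast on one
CPU.  Arrays are channels-last: (D, H, W, C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3D", "MaxPool3D", "Upsample3D", "UNet3D", "Adam", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.negative(np.abs(x), out=out)
    np.exp(out, out=out)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    neg = ~pos
    out[neg] = out[neg] / (1.0 + out[neg])
    return out


class Conv3D:
    """Same-padding stride-1 3D convolution (kernel 3 or 1), He-initialised."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        assert kernel in (1, 3)
        self.kernel = kernel
        self.cin, self.cout = cin, cout
        k3 = kernel ** 3
        scale = np.sqrt(2.0 / (k3 * cin))
        self.W = rng.normal(0.0, scale, (k3 * cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._shape: Tuple[int, int, int] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        if self.kernel == 1:
            return x.reshape(-1, self.cin)
        xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3, 3), axis=(0, 1, 2))
        # win: (D, H, W, C, 3, 3, 3) -> (N, 27*C) with kernel-major layout
        win = np.moveaxis(win, 3, -1)  # (D, H, W, 3, 3, 3, C)
        return np.ascontiguousarray(win).reshape(-1, 27 * self.cin)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape[:3]
        col = self._im2col(x.astype(np.float32, copy=False))
        self._col = col if train else None
        y = col @ self.W + self.b
        return y.reshape(*self._shape, self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        d, h, w = self._shape
        gyf = gy.reshape(-1, self.cout).astype(np.float32, copy=False)
        self.gW = self._col.T @ gyf
        self.gb = gyf.sum(axis=0)
        self._col = None
        if self.kernel == 1:
            return (gyf @ self.W.T).reshape(d, h, w, self.cin)
        # gradient wrt input = full correlation with the spatially flipped,
        # channel-transposed kernel
        Wk = self.W.reshape(3, 3, 3, self.cin, self.cout)
        Wt = Wk[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3).reshape(27 * self.cout, self.cin)
        gp = np.pad(gy.astype(np.float32, copy=False), ((1, 1), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(gp, (3, 3, 3), axis=(0, 1, 2))
        win = np.moveaxis(win, 3, -1)
        col = np.ascontiguousarray(win).reshape(-1, 27 * self.cout)
        return (col @ Wt).reshape(d, h, w, self.cin)

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)


class _Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class MaxPool3D:
    """2x2x2 max pooling; ties share the gradient equally."""

    def forward(self, x, train):
        d, h, w, c = x.shape
        xr = x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(1, 3, 5))
        self._xr = xr
        self._y = y
        return y

    def backward(self, gy):
        mask = self._xr == self._y[:, None, :, None, :, None, :]
        counts = mask.sum(axis=(1, 3, 5), keepdims=True)
        gx = mask * (gy[:, None, :, None, :, None, :] / counts)
        d2, _, h2, _, w2, _, c = self._xr.shape
        return gx.reshape(d2 * 2, h2 * 2, w2 * 2, c)


class Upsample3D:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train):
        return x.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy):
        d, h, w, c = gy.shape
        return gy.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))


class _Block:
    """conv -> ReLU -> dropout, twice."""

    def __init__(self, cin, cout, dropout, rng, drop_rng):
        self.layers = []
        for c_in in (cin, cout):
            self.layers += [Conv3D(c_in, cout, rng), _ReLU(), _Dropout(dropout, drop_rng)]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    @property
    def convs(self):
        return [l for l in self.layers if isinstance(l, Conv3D)]


@dataclass(frozen=True)
class NetSpec:
    """Architecture settings: ``depth`` pooling stages, ``base_filters``
    channels at full resolution, dropout rate on every convolution."""

    depth: int = 2
    base_filters: int = 8
    dropout: float = 0.2
    in_channels: int = 1
    # initial bias of the output layer, in logit units; setting it to the
    # logit of the expected foreground fraction keeps early training from
    # being dominated by the background class
    output_bias: float = 0.0


class UNet3D:
    """The encoder-decoder; see the module docstring for the layout."""

    def __init__(self, spec: NetSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        F = spec.base_filters
        self.enc: List[_Block] = []
        cin = spec.in_channels
        for i in range(spec.depth + 1):
            cout = F * 2 ** i
            self.enc.append(_Block(cin, cout, spec.dropout, rng, self._drop_rng))
            cin = cout
        self.pools = [MaxPool3D() for _ in range(spec.depth)]
        self.ups = [Upsample3D() for _ in range(spec.depth)]
        self.dec: List[_Block] = []
        for i in reversed(range(spec.depth)):
            skip_c = F * 2 ** i
            up_c = F * 2 ** (i + 1)
            self.dec.append(_Block(skip_c + up_c, skip_c, spec.dropout, rng, self._drop_rng))
        self.out_conv = Conv3D(F, 1, rng, kernel=1)
        self.out_conv.b[:] = spec.output_bias

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (D, H, W) or (D, H, W, 1) volume to a (D, H, W) probability
        map.  D, H, W must each be divisible by 2**depth."""
        if x.ndim == 3:
            x = x[..., None]
        if any(s % (2 ** self.spec.depth) for s in x.shape[:3]):
            raise ValueError(
                f"input shape {x.shape[:3]} not divisible by 2^depth={2 ** self.spec.depth}")
        skips = []
        h = x.astype(np.float32, copy=False)
        for i, block in enumerate(self.enc):
            h = block.forward(h, train)
            if i < self.spec.depth:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._skip_channels = []
        for j, block in enumerate(self.dec):
            up = self.ups[j].forward(h, train)
            skip = skips[-(j + 1)]
            self._skip_channels.append(skip.shape[-1])
            h = block.forward(np.concatenate([skip, up], axis=-1), train)
        logits = self.out_conv.forward(h, train)[..., 0]
        self._prob = sigmoid(logits)
        return self._prob

    def backward(self, gprob: np.ndarray) -> None:
        """Accumulate parameter gradients from dLoss/dprob of the last
        training-mode forward pass."""
        p = self._prob
        glogit = (gprob * p * (1.0 - p))[..., None].astype(np.float32)
        g = self.out_conv.backward(glogit)
        gskips = []
        for j in reversed(range(len(self.dec))):
            g = self.dec[j].backward(g)
            cs = self._skip_channels[j]
            gskip, gup = g[..., :cs], g[..., cs:]
            gskips.append(gskip)
            g = self.ups[j].backward(gup)
        gskips.reverse()  # gskips[j] pairs with skips[-(j+1)], i.e. enc level depth-1-j
        for i in reversed(range(len(self.enc))):
            if i < self.spec.depth:
                g = self.pools[i].backward(g)
                g = g + gskips[len(self.dec) - 1 - i]
            g = self.enc[i].backward(g)

    # -- parameter access ---------------------------------------------------
    def _conv_layers(self) -> List[Conv3D]:
        convs = []
        for block in self.enc + self.dec:
            convs += block.convs
        convs.append(self.out_conv)
        return convs

    def parameters(self) -> List[np.ndarray]:
        out = []
        for c in self._conv_layers():
            out += [c.W, c.b]
        return out

    def gradients(self) -> List[np.ndarray]:
        out = []
        for c in self._conv_layers():
            out += [c.gW, c.gb]
        return out

    def get_state(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: List[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * (g * g)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
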