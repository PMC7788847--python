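"""A small encoder-decoder segmentation network in pure numpy.

The architecture follows the classic U shape: repeated (conv3x3 + ReLU) x 2
blocks with 2x2 max-pooling on the way down, nearest-neighbour upsampling
with skip connections on the way up, and a 1x1 convolution head producing
per-pixel foreground logits. Forward and backward passes are written out
explicitly (im2col convolutions, argmax-routed pooling gradients) and
optimised with Adam. The network is intentionally tiny — a few thousand
parameters at the default depth 3 / 8 base channels — so that training on
64x64 rasters takes minutes on one CPU core and is bit-reproducible for a
fixed seed.

All tensors are NCHW float64. Spatial dimensions must be divisible by
2**depth (callers pad).
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "Adam", "bce_dice_loss", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (C*9, N*H*W) patch matrix for a 3x3 same-padded conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, 3, 3, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(cols).reshape(n, c * 9, h * w).transpose(1, 0, 2).reshape(c * 9, n * h * w)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    d = dcols.reshape(c, 3, 3, n, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2))
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + w] += d[:, i, j].transpose(1, 0, 2, 3)
    return dxp[:, :, 1:-1, 1:-1]


class Conv3x3:
    """Same-padded 3x3 convolution with He-initialised weights."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / (c_in * 9)), (c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = (self.W @ cols) + self.b[:, None]
        self._cache = (cols, x.shape)
        return out.reshape(-1, n, h * w).transpose(1, 0, 2).reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        d2 = dout.reshape(n, -1, h * w).transpose(1, 0, 2).reshape(dout.shape[1], -1)
        self.dW = d2 @ cols.T
        self.db = d2.sum(axis=1)
        dcols = self.W.T @ d2
        return _col2im(dcols, xshape)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), (c_out, c_in))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        out = np.einsum("oc,nchw->nohw", self.W, x)
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.dW = np.einsum("nohw,nchw->oc", dout, x)
        self.db = dout.sum(axis=(0, 2, 3))
        return np.einsum("oc,nohw->nchw", self.W, dout)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling; the gradient is routed to a single argmax per window."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xf = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        idx = xf.argmax(axis=-1)
        out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxf = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxf, idx[..., None], dout[..., None], axis=-1)
        return (
            dxf.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Upsample2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """(conv3x3 + ReLU) twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv3x3(c_in, c_out, rng)
        self.r1 = ReLU()
        self.c2 = Conv3x3(c_out, c_out, rng)
        self.r2 = ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))

    def params(self):
        return self.c1.params() + self.c2.params()


class UNet:
    """Encoder-decoder with skip connections for binary segmentation."""

    def __init__(self, depth: int = 3, base_channels: int = 8, in_channels: int = 1, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        chans = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        c_prev = in_channels
        for i in range(depth):
            self.enc.append(_Block(c_prev, chans[i], rng))
            c_prev = chans[i]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(c_prev, chans[depth], rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        c_prev = chans[depth]
        for i in reversed(range(depth)):
            self.dec.append(_Block(c_prev + chans[i], chans[i], rng))
            c_prev = chans[i]
        self.head = Conv1x1(chans[0], 1, rng)
        self._skip_channels = [chans[i] for i in reversed(range(depth))]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x (N,1,H,W) with H, W divisible by 2**depth -> logits (N,1,H,W)."""
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for blk, up, c_skip in zip(reversed(self.dec), reversed(self.ups), reversed(self._skip_channels)):
            d = blk.backward(d)
            dskips.append(d[:, :c_skip])
            d = up.backward(d[:, c_skip:])
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = pool.backward(d) + dskip
            d = blk.backward(d)

    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError("checkpoint parameter count mismatch")
        for (p, _), a in zip(own, arrays):
            if p.shape != a.shape:
                raise ValueError(f"checkpoint shape mismatch: {p.shape} vs {a.shape}")
            p[...] = a


class Adam:
    def __init__(self, net: UNet, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.net.params()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_dice_loss(
    logits: np.ndarray, target: np.ndarray, mode: str = "sum", eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Binary cross-entropy and/or soft-Dice loss with its logit gradient.

    Parameters
    ----------
    logits, target : (N,1,H,W) arrays; target is {0,1}.
    mode : "cross-entropy", "dice", or "sum" (their sum).

    Returns
    -------
    (loss value, d loss / d logits)
    """
    if mode not in ("cross-entropy", "dice", "sum"):
        raise ValueError(f"unknown loss mode {mode!r}")
    p = sigmoid(logits)
    n = logits.shape[0]
    npx = logits.size
    loss = 0.0
    dlogits = np.zeros_like(logits)
    if mode in ("cross-entropy", "sum"):
        z, y = logits, target
        bce = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
        loss += float(bce.mean())
        dlogits += (p - y) / npx
    if mode in ("dice", "sum"):
        axes = (1, 2, 3)
        inter = (p * target).sum(axis=axes)
        denom = p.sum(axis=axes) + target.sum(axis=axes)
        dice = (2 * inter + eps) / (denom + eps)
        loss += float((1.0 - dice).mean())
        # d(1-dice)/dp, averaged over the batch, chained through the sigmoid
        dp = -(2 * target * (denom + eps)[:, None, None, None] - (2 * inter + eps)[:, None, None, None]) / (
            (denom + eps) ** 2
        )[:, None, None, None]
        dlogits += dp / n * p * (1 - p)
    return loss, dlogits
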