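"""A small CPU conv-net core: layers, U-Net graph, softmax loss and Adam.

Everything runs in float32 on numpy. Convolutions go through
``sliding_window_view`` + ``tensordot`` so the heavy lifting lands in BLAS;
at the desk-scale profile used throughout (96x96 inputs, base width 8) a
forward+backward pass over one image takes a few hundred MFLOPs, which keeps
full training runs in the minutes range on one core.

The U-Net here is the classic encoder-decoder with skip concatenation:
``depth`` resolution levels, two 3x3 convolutions (ReLU) per level, 2x2 max
pooling on the way down, 2x2 transposed convolution on the way up, and a
final 1x1 projection to class logits.  Convolutions are zero-padded so the
logit grid matches the input grid exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2d:
    """kxk convolution, stride 1, zero padding to 'same' size."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.k = k
        self.p = k // 2
        self._win: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        self._win = win
        y = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = self._win
        self.dW = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3])).astype(F32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(F32)
        p = self.p
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        dwin = sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        Wf = self.W[:, :, ::-1, ::-1]
        dx = np.tensordot(dwin, Wf, axes=([1, 4, 5], [0, 2, 3]))
        self._win = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dy, F32(0))
        self._mask = None
        return out


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        self._idx = idx
        self._shape = x.shape
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        xr = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(xr.reshape(n, c, h, w))


class UpConv2:
    """2x2 transposed convolution, stride 2 (doubles spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = (rng.standard_normal((c_in, c_out, 2, 2)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        y = np.tensordot(x, self.W, axes=([1], [0]))  # (n,h,w,c_out,2,2)
        y = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.W.shape[1], 2 * h, 2 * w)
        return np.ascontiguousarray(y) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, co, H, W_ = dy.shape
        h, w = H // 2, W_ // 2
        dyr = dy.reshape(n, co, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (n,h,w,co,2,2)
        x = self._x
        self.dW = np.tensordot(x, dyr, axes=([0, 2, 3], [0, 1, 2])).astype(F32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(F32)
        dx = np.tensordot(dyr, self.W, axes=([3, 4, 5], [1, 2, 3]))  # (n,h,w,c_in)
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        return [("W", self), ("b", self)]


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv2d(c_in, c_out, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(c_out, c_out, 3, rng)
        self.r2 = ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))

    def params(self):
        return self.c1.params() + self.c2.params()


class UNet:
    """Encoder-decoder segmentation network with skip connections.

    Parameters
    ----------
    n_classes
        Output classes (softmax over this axis downstream).
    depth
        Number of resolution levels including the bottleneck; the input side
        must be divisible by ``2**(depth-1)``.
    base_width
        Channels at the top level; doubled at each level down.
    """

    def __init__(self, n_classes: int, depth: int = 5, base_width: int = 8,
                 in_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = [base_width * 2 ** i for i in range(depth)]
        self.depth = depth
        self.enc: list[_Block] = []
        c = in_channels
        for w in widths:
            self.enc.append(_Block(c, w, rng))
            c = w
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups: list[UpConv2] = []
        self.dec: list[_Block] = []
        for i in range(depth - 2, -1, -1):
            self.ups.append(UpConv2(widths[i + 1], widths[i], rng))
            self.dec.append(_Block(2 * widths[i], widths[i], rng))
        self.head = Conv2d(widths[0], n_classes, 1, rng)
        self.n_classes = n_classes

    # -- graph ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of shape (n, n_classes, h, w) for input (n, c, h, w)."""
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x)
            if i < self.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = blk.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, blk in zip(reversed(self.ups), reversed(self.dec)):
            d = blk.backward(dx)
            c = d.shape[1] // 2
            dskips.append(d[:, :c])
            dx = up.backward(d[:, c:])
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                dx = self.pools[i].backward(dx) + dskips[i]
            dx = self.enc[i].backward(dx)

    # -- parameters -------------------------------------------------------
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        for up in self.ups:
            out += up.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [getattr(layer, name) for name, layer in self.params()]

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (name, layer), arr in zip(self.params(), state):
            setattr(layer, name, np.asarray(arr, dtype=F32).copy())


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=axis, keepdims=True)).astype(F32)


def softmax_ce_loss(logits: np.ndarray, target: np.ndarray,
                    fp_penalty: float = 0.0, caries_class: int = 1,
                    ) -> tuple[float, np.ndarray]:
    """Pixelwise cross-entropy with an optional false-positive penalty term.

    ``target`` is an integer class map of shape (n, h, w).  When
    ``fp_penalty`` (lambda) is nonzero, images whose target contains no pixel
    of ``caries_class`` contribute an extra ``lambda * mean p_caries`` —
    the mean predicted caries probability over all their pixels — punishing
    caries predictions on caries-free images.

    Returns (scalar loss, dL/dlogits).
    """
    n, c, h, w = logits.shape
    p = softmax(logits)
    npix = h * w
    eps = 1e-12
    idx = np.arange(c)[None, :, None, None] == target[:, None]
    ce = -np.log(np.clip(p, eps, None))[idx].sum() / (n * npix)
    dlog = (p - idx.astype(F32)) / F32(n * npix)

    loss = float(ce)
    if fp_penalty > 0.0:
        empty = ~(target == caries_class).any(axis=(1, 2))  # (n,)
        if empty.any():
            pc = p[:, caries_class]  # (n,h,w)
            pen = pc[empty].mean(axis=(1, 2)).sum() / n
            loss += fp_penalty * float(pen)
            # d(mean p_c)/dz_k = p_c * (delta_{k,c} - p_k) / npix per image
            g = np.zeros_like(dlog)
            pe = p[empty]
            pce = pc[empty][:, None]
            g_e = -pce * pe
            g_e[:, caries_class] += pc[empty]
            g[empty] = g_e / F32(npix)
            dlog += F32(fp_penalty / n) * g
    return loss, dlog.astype(F32)


@dataclass
class Adam:
    """Adaptive moment estimation over a model's parameter list."""

    model: UNet
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)

    def __post_init__(self):
        for arr in self.model.state_arrays():
            self.m.append(np.zeros_like(arr))
            self.v.append(np.zeros_like(arr))

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (name, layer) in enumerate(self.model.params()):
            g = getattr(layer, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            arr = getattr(layer, name)
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
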