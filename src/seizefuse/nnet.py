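"""Neural-network layers and optimizers on the autodiff engine.

Linear, 1-D/2-D convolution (im2col), non-overlapping max pooling, LSTM /
bidirectional LSTM, dropout, and Adam/SGD.  Initialization follows the
uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) convention and is driven by an
explicit numpy Generator so that a fixed seed reproduces parameters
bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, concat, stack_time

__all__ = [
    "Module", "Linear", "Conv1d", "Conv2d", "MaxPool1d", "MaxPool2d",
    "LSTM", "BiLSTM", "Dropout", "Sequential", "Adam", "SGD",
    "conv1d", "conv2d", "maxpool1d", "maxpool2d",
]


# -- functional conv / pool ---------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor, pad: int = 0) -> Tensor:
    """x (B,C,L), w (F,C,K), b (F,) -> (B,F,Lout), stride 1."""
    B, C, L = x.data.shape
    F, _, K = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    Lout = L + 2 * pad - K + 1
    win = sliding_window_view(xp, K, axis=2)            # (B,C,Lout,K)
    cols = win.transpose(0, 2, 1, 3).reshape(B * Lout, C * K)
    wmat = w.data.reshape(F, C * K).T
    out = (cols @ wmat + b.data).reshape(B, Lout, F).transpose(0, 2, 1)

    def backward(g):
        gm = g.transpose(0, 2, 1).reshape(B * Lout, F)
        if w.requires_grad:
            w._accum((cols.T @ gm).T.reshape(F, C, K))
        if b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wmat.T).reshape(B, Lout, C, K).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, :, k:k + Lout] += dcols[:, :, :, k]
            x._accum(dxp[:, :, pad:pad + L])

    return Tensor._node(out, (x, w, b), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int = 0) -> Tensor:
    """x (B,C,H,W), w (F,C,KH,KW), b (F,) -> (B,F,Ho,Wo), stride 1."""
    B, C, H, W = x.data.shape
    F, _, KH, KW = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho, Wo = H + 2 * pad - KH + 1, W + 2 * pad - KW + 1
    win = sliding_window_view(xp, (KH, KW), axis=(2, 3))  # (B,C,Ho,Wo,KH,KW)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * KH * KW)
    wmat = w.data.reshape(F, C * KH * KW).T
    out = (cols @ wmat + b.data).reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, F)
        if w.requires_grad:
            w._accum((cols.T @ gm).T.reshape(F, C, KH, KW))
        if b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wmat.T).reshape(B, Ho, Wo, C, KH, KW).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for kh in range(KH):
                for kw in range(KW):
                    dxp[:, :, kh:kh + Ho, kw:kw + Wo] += dcols[:, :, :, :, kh, kw]
            x._accum(dxp[:, :, pad:pad + H, pad:pad + W])

    return Tensor._node(out, (x, w, b), backward)


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pool; a trailing remainder is dropped."""
    if k <= 1:
        return x
    B, C, L = x.data.shape
    Lo = L // k
    blocks = x.data[:, :, :Lo * k].reshape(B, C, Lo, k)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        db = np.zeros((B, C, Lo, k))
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, :Lo * k] = db.reshape(B, C, Lo * k)
        x._accum(dx)

    return Tensor._node(out, (x,), backward)


def maxpool2d(x: Tensor, kh: int, kw: int) -> Tensor:
    if kh <= 1 and kw <= 1:
        return x
    B, C, H, W = x.data.shape
    Ho, Wo = H // kh, W // kw
    blocks = x.data[:, :, :Ho * kh, :Wo * kw].reshape(B, C, Ho, kh, Wo, kw)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, kh * kw)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        db = np.zeros((B, C, Ho, Wo, kh * kw))
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        db = db.reshape(B, C, Ho, Wo, kh, kw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros_like(x.data)
        dx[:, :, :Ho * kh, :Wo * kw] = db.reshape(B, C, Ho * kh, Wo * kw)
        x._accum(dx)

    return Tensor._node(out, (x,), backward)


# -- modules ------------------------------------------------------------------

class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        params.extend(u.parameters())
                    elif isinstance(u, Tensor) and u.requires_grad:
                        params.append(u)
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        u.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data[...] = s

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    s = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-s, s, shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _uniform(rng, (n_in, n_out), n_in)
        self.b = _uniform(rng, (n_out,), n_in)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng, pad: int | None = None):
        self.k, self.pad = k, k // 2 if pad is None else pad
        self.w = _uniform(rng, (c_out, c_in, k), c_in * k)
        self.b = _uniform(rng, (c_out,), c_in * k)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, self.pad)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng, pad: int | None = None):
        self.k, self.pad = k, k // 2 if pad is None else pad
        self.w = _uniform(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = _uniform(rng, (c_out,), c_in * k * k)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.pad)


class MaxPool1d(Module):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        # pooling is skipped once the length would vanish
        return maxpool1d(x, self.k) if x.data.shape[-1] >= self.k else x


class MaxPool2d(Module):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        kh = self.k if x.data.shape[-2] >= self.k else 1
        kw = self.k if x.data.shape[-1] >= self.k else 1
        return maxpool2d(x, kh, kw)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, x.data.shape) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class _Relu(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


def relu_layer() -> Module:
    return _Relu()


class LSTM(Module):
    """Single-direction LSTM; input (T, B, C), returns outputs (T, B, H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = _uniform(rng, (n_in, 4 * hidden), n_in)
        self.wh = _uniform(rng, (hidden, 4 * hidden), hidden)
        self.b = _uniform(rng, (4 * hidden,), hidden)

    def forward(self, x: Tensor) -> Tensor:
        T, B, C = x.data.shape
        H = self.hidden
        proj = (x.reshape(T * B, C) @ self.wx).reshape(T, B, 4 * H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            z = proj.index0(t) + h @ self.wh + self.b
            i = z.narrow(-1, 0, H).sigmoid()
            f = z.narrow(-1, H, H).sigmoid()
            g = z.narrow(-1, 2 * H, H).tanh()
            o = z.narrow(-1, 3 * H, H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return stack_time(outs)


class BiLSTM(Module):
    """Forward and backward LSTM over time; outputs (T, B, 2H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.fw = LSTM(n_in, hidden, rng)
        self.bw = LSTM(n_in, hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        out_f = self.fw(x)
        out_b = self.bw(x.flip0()).flip0()
        return concat([out_f, out_b], axis=-1)


# -- optimizers ---------------------------------------------------------------

class SGD:
    def __init__(self, params: list[Tensor], lr: float):
        self.params, self.lr = list(params), lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params, self.lr = list(params), lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
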