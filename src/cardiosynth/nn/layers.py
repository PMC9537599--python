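"""Neural-network building blocks on top of the autodiff core.

Conventions: images are NCHW float32; parameters are ``Tensor`` leaves with
``requires_grad=True``; every layer takes an ``np.random.Generator`` for
initialization so whole networks are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self):
        params, seen = [], set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def n_parameters(self):
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self):
        """Flat list of parameter arrays, in stable discovery order."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr):
    return Tensor(np.asarray(arr, dtype=np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / n_in)
        self.weight = _param(rng.normal(0.0, scale or 1e-8, (n_in, n_out)))
        self.bias = _param(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class Conv2d(Module):
    """k x k convolution via im2col; stride/padding as in the usual libraries."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 zero_init: bool = False, init_scale: float = 1.0):
        if padding is None:
            padding = k // 2
        fan_in = c_in * k * k
        scale = 0.0 if zero_init else init_scale * np.sqrt(2.0 / fan_in)
        self.weight = _param(rng.normal(0.0, scale or 1e-8, (c_out, fan_in)))
        self.bias = _param(np.zeros(c_out))
        self.k, self.stride, self.padding = k, stride, padding
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        Ho = (H + 2 * self.padding - self.k) // self.stride + 1
        Wo = (W + 2 * self.padding - self.k) // self.stride + 1
        cols = ad.unfold(x, self.k, self.stride, self.padding)   # (N,Ckk,L)
        y = ad.matmul(self.weight, cols)                         # (N,c_out,L)
        y = y + self.bias.reshape(1, self.c_out, 1)
        return y.reshape(N, self.c_out, Ho, Wo)


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.groups, self.eps, self.channels = groups, eps, channels
        self.gamma = _param(np.ones((1, channels, 1, 1)))
        self.beta = _param(np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        xn = ad.group_norm(x, self.groups, self.eps)
        return xn * self.gamma + self.beta


class SelfAttention2d(Module):
    """Single-head spatial self-attention (1x1 projections, residual add)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.norm = GroupNorm(channels)
        self.qkv = Linear(channels, 3 * channels, rng)
        self.proj = Linear(channels, channels, rng, zero_init=True)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        h = self.norm(x).reshape(N, C, H * W).swapaxes(1, 2)     # (N,L,C)
        qkv = self.qkv(h)
        q = ad.narrow(qkv, 2, 0, C)
        k = ad.narrow(qkv, 2, C, C)
        v = ad.narrow(qkv, 2, 2 * C, C)
        att = ad.matmul(q, k.swapaxes(1, 2)) * (1.0 / np.sqrt(C))
        att = ad.softmax_lastdim(att)
        out = self.proj(ad.matmul(att, v))                       # (N,L,C)
        out = out.swapaxes(1, 2).reshape(N, C, H, W)
        return x + out


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def state(self):
        return {"m": self.m, "v": self.v, "t": self.t}

    def load_state(self, state):
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
        self.t = int(state["t"])
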