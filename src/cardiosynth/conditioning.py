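"""Scalar-covariate conditioning.

A scalar covariate (an age gap in years, a BMI gap, a cardiac-phase index)
is first lifted to a fixed-length vector with the Transformer-style
sinusoidal embedding and then injected into a network by *conditional
biasing*: a learned per-block projection maps the embedding to one scalar
per feature channel, which is added to the channel's feature map just
before that block's group normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor
from .nn import autodiff as ad


@dataclass(frozen=True)
class CovariatePair:
    """Source value, target value, and their gap (target - source)."""

    a_s: float
    a_t: float

    @property
    def a_d(self) -> float:
        return self.a_t - self.a_s


def sinusoidal_embed(value: float, d: int, scale_constant: float = 10000.0
                     ) -> np.ndarray:
    """Sinusoidal embedding of a scalar.

    ``e[2i] = sin(value / C**(2i/d))`` and ``e[2i+1] = cos(value / C**(2i/d))``
    for ``i = 0 .. d/2 - 1``, with ``C = scale_constant``.  Every component
    lies in [-1, 1]; the map is continuous and, for d >= 8, injective over
    the covariate ranges used here.
    """
    if d % 2 or d < 2:
        raise ValueError(f"embedding length must be even and >= 2, got {d}")
    value = float(value)
    if not np.isfinite(value):
        raise ValueError("covariate value must be finite")
    i = np.arange(d // 2, dtype=np.float64)
    freq = value / scale_constant ** (2.0 * i / d)
    out = np.empty(d, dtype=np.float64)
    out[0::2] = np.sin(freq)
    out[1::2] = np.cos(freq)
    return out


def embed_batch(values, d: int, scale_constant: float = 10000.0) -> np.ndarray:
    return np.stack([sinusoidal_embed(v, d, scale_constant) for v in
                     np.atleast_1d(np.asarray(values, dtype=np.float64))])


def conditional_bias(features: Tensor, bias: Tensor) -> Tensor:
    """Add one scalar per channel to an NCHW feature map.

    ``bias`` has shape (N, C) or (C,); the result keeps the feature shape.
    """
    if features.ndim != 4:
        raise ValueError("features must be NCHW")
    c = features.shape[1]
    if bias.shape[-1] != c:
        raise ValueError(
            f"bias length {bias.shape[-1]} != channel count {c}")
    if bias.ndim == 1:
        b = bias.reshape(1, c, 1, 1)
    else:
        b = bias.reshape(bias.shape[0], c, 1, 1)
    return features + b


class CovariateMLP(Module):
    """Shared trunk: sinusoidal embedding -> linear -> SiLU -> linear."""

    def __init__(self, d_embed: int, d_hidden: int, rng: np.random.Generator,
                 scale_constant: float = 10000.0):
        self.d_embed = d_embed
        self.scale_constant = scale_constant
        self.fc1 = Linear(d_embed, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_hidden, rng)

    def forward(self, values) -> Tensor:
        e = embed_batch(values, self.d_embed, self.scale_constant)
        h = ad.silu(self.fc1(Tensor(e.astype(np.float32))))
        return self.fc2(h)


class BiasProjection(Module):
    """Per-block linear head mapping the shared embedding to one bias per
    channel; each residual block owns its own instance so different
    resolutions can learn different conditionings."""

    def __init__(self, d_hidden: int, channels: int, rng: np.random.Generator):
        self.proj = Linear(d_hidden, channels, rng)

    def forward(self, emb: Tensor) -> Tensor:
        return self.proj(ad.silu(emb))
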