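"""Generator and critic networks.

The generator is a U-Net of residual blocks with single-head self-attention
at the coarsest resolutions (the backbone family popularized by diffusion
models).  It does not emit an image directly: it emits a bounded residual
*mapping* m in [-1, 1] (tanh-bounded so gradients flow), and the synthesized
image is ``clip(x + m, 0, 1)``.  Conditioning on the covariate gap enters
every residual block by conditional biasing.

The critic mirrors the generator's encoder, is conditioned on the covariate
of the presented image (its true value for real images, the target value for
synthesized ones), and pools adaptively to a single scalar score per image.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .conditioning import BiasProjection, CovariateMLP, conditional_bias
from .nn import (Conv2d, GroupNorm, Linear, Module, SelfAttention2d, Tensor)
from .nn import autodiff as ad


@dataclass(frozen=True)
class NetConfig:
    image_size: int = 128
    base_width: int = 32
    channel_mults: tuple = (1, 2, 2, 4)
    blocks_per_level: int = 2
    attention_resolutions: tuple = (16, 8)
    embed_dim: int = 32
    cond_hidden: int = 64
    groups: int = 8
    covariate_scale: float = 1.0   # divide covariate before embedding

    @property
    def levels(self) -> int:
        return len(self.channel_mults)

    def to_dict(self):
        d = asdict(self)
        d["channel_mults"] = list(self.channel_mults)
        d["attention_resolutions"] = list(self.attention_resolutions)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["channel_mults"] = tuple(d["channel_mults"])
        d["attention_resolutions"] = tuple(d["attention_resolutions"])
        return cls(**d)


def toy_config(image_size: int = 32, base_width: int = 8) -> NetConfig:
    """Small configuration for CPU-scale experiments."""
    return NetConfig(image_size=image_size, base_width=base_width,
                     channel_mults=(1, 2), blocks_per_level=1,
                     attention_resolutions=(image_size // 4,),
                     embed_dim=16, cond_hidden=32, groups=4)


@dataclass
class SynthesisResult:
    """Input image, bounded residual mapping, and transformed image."""

    x: np.ndarray          # [0, 1]
    mapping: np.ndarray    # [-1, 1]
    output: np.ndarray     # clip(x + mapping, 0, 1)

    def recompute_output(self) -> np.ndarray:
        return np.clip(self.x + self.mapping, 0.0, 1.0)


class ResidualBlock(Module):
    """GN -> SiLU -> conv, conditional bias, GN -> SiLU -> conv, skip.

    The covariate bias is added immediately before the second group
    normalization; each block owns its own projection head."""

    def __init__(self, c_in, c_out, cond_hidden, rng, groups=8):
        self.norm1 = GroupNorm(c_in, groups)
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bias_proj = BiasProjection(cond_hidden, c_out, rng)
        self.norm2 = GroupNorm(c_out, groups)
        # small (but nonzero) residual-branch init: near-identity start
        # while keeping the conditioning path live from the first step
        self.conv2 = Conv2d(c_out, c_out, 3, rng, init_scale=0.1)
        self.skip = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None

    def forward(self, x: Tensor, emb: Tensor) -> Tensor:
        h = self.conv1(ad.silu(self.norm1(x)))
        h = conditional_bias(h, self.bias_proj(emb))
        h = self.conv2(ad.silu(self.norm2(h)))
        s = self.skip(x) if self.skip is not None else x
        return h + s


def _validate_input(x: np.ndarray, levels: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError(f"expected single-channel images, got {x.shape}")
    n, _, h, w = x.shape
    if h != w:
        raise ValueError(f"images must be square, got {h}x{w}")
    div = 2 ** (levels - 1)
    if h % div:
        raise ValueError(f"image size {h} not divisible by {div}")
    if x.min() < -1e-6 or x.max() > 1 + 1e-6:
        raise ValueError("input images must be normalized to [0, 1]")
    return x


class GeneratorNet(Module):
    """Encoder-decoder producing the bounded residual mapping."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        cfg = self.config = config
        self.cond = CovariateMLP(cfg.embed_dim, cfg.cond_hidden, rng)
        w = cfg.base_width
        self.stem = Conv2d(1, w, 3, rng)
        self.down_blocks, self.down_attn, self.downs = [], [], []
        chans = [w]
        c = w
        res = cfg.image_size
        for lvl, mult in enumerate(cfg.channel_mults):
            c_out = w * mult
            blocks, attns = [], []
            for _ in range(cfg.blocks_per_level):
                blocks.append(ResidualBlock(c, c_out, cfg.cond_hidden, rng,
                                            cfg.groups))
                attns.append(SelfAttention2d(c_out, rng)
                             if res in cfg.attention_resolutions else None)
                c = c_out
            self.down_blocks.append(blocks)
            self.down_attn.append(attns)
            chans.append(c)
            if lvl < cfg.levels - 1:
                self.downs.append(Conv2d(c, c, 3, rng, stride=2))
                res //= 2
        self.mid1 = ResidualBlock(c, c, cfg.cond_hidden, rng, cfg.groups)
        self.mid_attn = SelfAttention2d(c, rng)
        self.mid2 = ResidualBlock(c, c, cfg.cond_hidden, rng, cfg.groups)
        self.up_blocks, self.up_attn, self.ups = [], [], []
        for lvl in reversed(range(cfg.levels)):
            c_skip = w * cfg.channel_mults[lvl]
            c_out = c_skip
            blocks, attns = [], []
            for _ in range(cfg.blocks_per_level):
                blocks.append(ResidualBlock(c + c_skip, c_out,
                                            cfg.cond_hidden, rng, cfg.groups))
                attns.append(SelfAttention2d(c_out, rng)
                             if res in cfg.attention_resolutions else None)
                c = c_out
                c_skip = 0  # only the first block of the level concatenates
            self.up_blocks.append(blocks)
            self.up_attn.append(attns)
            if lvl > 0:
                self.ups.append(Conv2d(c, c, 3, rng))
                res *= 2
        self.out_norm = GroupNorm(c, cfg.groups)
        self.out_conv = Conv2d(c, 1, 3, rng, zero_init=True)

    def forward_t(self, x: Tensor, a_d) -> Tensor:
        """Mapping tensor in [-1, 1] for a batch (graph-connected)."""
        cfg = self.config
        a = np.atleast_1d(np.asarray(a_d, dtype=np.float64))
        if a.size == 1 and x.shape[0] > 1:
            a = np.full(x.shape[0], a.item())
        emb = self.cond(a / cfg.covariate_scale)
        h = self.stem(x)
        skips = []
        for lvl in range(cfg.levels):
            for blk, attn in zip(self.down_blocks[lvl], self.down_attn[lvl]):
                h = blk(h, emb)
                if attn is not None:
                    h = attn(h)
            skips.append(h)
            if lvl < cfg.levels - 1:
                h = self.downs[lvl](h)
        h = self.mid1(h, emb)
        h = self.mid_attn(h)
        h = self.mid2(h, emb)
        for i, lvl in enumerate(reversed(range(cfg.levels))):
            h = ad.concat([h, skips[lvl]], axis=1)
            for blk, attn in zip(self.up_blocks[i], self.up_attn[i]):
                h = blk(h, emb)
                if attn is not None:
                    h = attn(h)
            if lvl > 0:
                h = ad.upsample_nearest2(h)
                h = self.ups[i](h)
        out = self.out_conv(ad.silu(self.out_norm(h)))
        return ad.tanh(out)

    def synth_t(self, x: Tensor, a_d) -> tuple[Tensor, Tensor]:
        """(mapping, clipped output) as graph tensors."""
        m = self.forward_t(x, a_d)
        return m, ad.clip(x + m, 0.0, 1.0)

    def synthesize(self, x: np.ndarray, a_d) -> SynthesisResult:
        """Deterministic inference: numpy in, `SynthesisResult` out."""
        xv = _validate_input(x, self.config.levels)
        m, out = self.synth_t(Tensor(xv), a_d)
        squeeze = np.asarray(x).ndim == 2
        md, od, xd = m.data[:, 0], out.data[:, 0], xv[:, 0]
        if squeeze:
            md, od, xd = md[0], od[0], xd[0]
        return SynthesisResult(x=xd, mapping=md, output=od)


class CriticNet(Module):
    """Encoder + adaptive pooling to one scalar score per image."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        cfg = self.config = config
        self.cond = CovariateMLP(cfg.embed_dim, cfg.cond_hidden, rng)
        w = cfg.base_width
        self.stem = Conv2d(1, w, 3, rng)
        self.blocks, self.attn, self.downs = [], [], []
        c = w
        res = cfg.image_size
        for lvl, mult in enumerate(cfg.channel_mults):
            c_out = w * mult
            blocks, attns = [], []
            for _ in range(cfg.blocks_per_level):
                blocks.append(ResidualBlock(c, c_out, cfg.cond_hidden, rng,
                                            cfg.groups))
                attns.append(SelfAttention2d(c_out, rng)
                             if res in cfg.attention_resolutions else None)
                c = c_out
            self.blocks.append(blocks)
            self.attn.append(attns)
            if lvl < cfg.levels - 1:
                self.downs.append(Conv2d(c, c, 3, rng, stride=2))
                res //= 2
        self.out_norm = GroupNorm(c, cfg.groups)
        self.head = Linear(c, 1, rng)

    def forward_t(self, x: Tensor, a) -> Tensor:
        """Scalar scores, shape (N,), differentiable w.r.t. ``x``."""
        cfg = self.config
        av = np.atleast_1d(np.asarray(a, dtype=np.float64))
        if av.size == 1 and x.shape[0] > 1:
            av = np.full(x.shape[0], av.item())
        emb = self.cond(av / cfg.covariate_scale)
        h = self.stem(x)
        for lvl in range(cfg.levels):
            for blk, attn in zip(self.blocks[lvl], self.attn[lvl]):
                h = blk(h, emb)
                if attn is not None:
                    h = attn(h)
            if lvl < cfg.levels - 1:
                h = self.downs[lvl](h)
        h = ad.silu(self.out_norm(h))
        pooled = h.mean(axis=(2, 3))            # adaptive average pool
        score = self.head(pooled)               # (N, 1)
        if not np.all(np.isfinite(score.data)):
            raise FloatingPointError("non-finite critic score at head layer")
        return score.reshape(score.shape[0])

    def score(self, x: np.ndarray, a) -> np.ndarray:
        xv = _validate_input(x, self.config.levels)
        return self.forward_t(Tensor(xv), a).data.copy()


def generator_forward(generator: GeneratorNet, x: np.ndarray, a_d
                      ) -> SynthesisResult:
    """Functional synthesis wrapper (validates bounds and shape)."""
    return generator.synthesize(x, a_d)


def critic_forward(critic: CriticNet, x: np.ndarray, a) -> np.ndarray:
    return critic.score(x, a)
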