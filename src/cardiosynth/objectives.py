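"""Adversarial, gradient-penalty and cycle-consistency objectives.

The critic is trained to maximize the Wasserstein surrogate
``E[D(x, a)] - E[D(x_gen, a_t)]`` subject to a gradient penalty
``lambda_GP * E[(||grad_xhat D(xhat, a_t)||_2 - 1)^2]`` evaluated at random
points ``xhat = eps*x + (1-eps)*x_gen`` on the line connecting real and
generated samples (eps ~ U(0,1), drawn independently per batch element).
The generator is trained to minimize ``-E[D(x_gen, a_t)]`` plus a
cycle-consistency L1 term: shifting a covariate by +a_d and then by -a_d
must reproduce the input.

The min-max objective is realized by alternating updates: the critic
minimizes (core + lambda_GP * gp), the generator minimizes
(adversarial + lambda_cc * cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, grad
from .nn import autodiff as ad


@dataclass(frozen=True)
class LossWeights:
    """Penalty weights: gradient penalty defaults to 10, cycle term to 1."""

    gp: float = 10.0
    cc: float = 1.0

    def __post_init__(self):
        if self.gp < 0 or self.cc < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossReport:
    critic_core: float | None = None
    gp: float | None = None
    cycle: float | None = None
    generator_adv: float | None = None
    critic_total: float | None = None
    generator_total: float | None = None
    lambda_gp: float = 10.0
    lambda_cc: float = 1.0

    def as_dict(self):
        return {k: v for k, v in self.__dict__.items()}


def _as_batch(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    return x


def interpolate(x_real: np.ndarray, x_gen: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Random points on the segments joining real and generated samples."""
    if x_real.shape != x_gen.shape:
        raise ValueError(
            f"shape mismatch {x_real.shape} vs {x_gen.shape}")
    eps = rng.uniform(0.0, 1.0, (x_real.shape[0],) + (1,) *
                      (x_real.ndim - 1)).astype(x_real.dtype)
    return eps * x_real + (1.0 - eps) * x_gen


def gradient_penalty_t(critic, x_real, x_gen, a_t, rng) -> Tensor:
    """Graph-connected penalty; differentiable w.r.t. critic parameters."""
    x_real, x_gen = _as_batch(x_real), _as_batch(x_gen)
    x_hat = Tensor(interpolate(x_real, x_gen, rng), requires_grad=True)
    scores = critic.forward_t(x_hat, a_t)
    gx = grad(scores.sum(), [x_hat], create_graph=True)[0]
    n = x_hat.shape[0]
    sq = (gx * gx).reshape(n, int(np.prod(x_hat.shape[1:])))
    norms = ad.sqrt(sq.sum(axis=1) + 1e-12)
    dev = norms - 1.0
    return (dev * dev).mean()


def gradient_penalty(critic, x_real, x_gen, a_t, rng_seed: int = 0) -> float:
    """Mean over the batch of ``(||grad_xhat D(xhat, a_t)||_2 - 1)^2``."""
    rng = np.random.default_rng(rng_seed)
    return float(gradient_penalty_t(critic, x_real, x_gen, a_t, rng).item())


def cycle_loss_t(generator, x, a_d, x_fwd: Tensor | None = None) -> Tensor:
    """L1 reconstruction after a +a_d then -a_d round trip.

    ``x_fwd`` may pass in an already synthesized forward image to avoid
    recomputing it.
    """
    xb = _as_batch(x)
    xt = Tensor(xb)
    if x_fwd is None:
        _, x_fwd = generator.synth_t(xt, a_d)
    _, x_rec = generator.synth_t(x_fwd, -np.asarray(a_d, dtype=np.float64))
    return ad.absval(xt - x_rec).mean()


def cycle_loss(generator, x, a_d) -> float:
    return float(cycle_loss_t(generator, x, a_d).item())


def critic_loss_t(critic, generator, x_real_s, a_s, x_real_t, a_t_real,
                  a_d, rng, weights: LossWeights = LossWeights()):
    """Critic objective on one minibatch (to be minimized by the critic).

    ``x_real_s``/``a_s`` feed the generator with gaps ``a_d`` (target ages
    ``a_s + a_d``); ``x_real_t``/``a_t_real`` is an independent real batch
    presented with its own true covariates.
    """
    xs, xt = _as_batch(x_real_s), _as_batch(x_real_t)
    if xs.shape[0] != xt.shape[0]:
        raise ValueError(
            f"batch size mismatch: {xs.shape[0]} vs {xt.shape[0]}")
    a_s = np.atleast_1d(np.asarray(a_s, dtype=np.float64))
    a_d = np.atleast_1d(np.asarray(a_d, dtype=np.float64))
    a_t_gen = a_s + a_d
    _, x_gen = generator.synth_t(Tensor(xs), a_d)
    x_gen = x_gen.detach()
    score_gen = critic.forward_t(x_gen, a_t_gen)
    score_real = critic.forward_t(Tensor(xt), a_t_real)
    core = score_gen.mean() - score_real.mean()
    gp = gradient_penalty_t(critic, xt, x_gen.data, a_t_gen, rng)
    total = core + weights.gp * gp
    report = LossReport(critic_core=float(core.item()),
                        gp=float(gp.item()),
                        critic_total=float(total.item()),
                        lambda_gp=weights.gp, lambda_cc=weights.cc)
    return total, report


def critic_loss(critic, generator, x_real_s, a_s, x_real_t, a_t_real,
                a_d=None, weights: LossWeights = LossWeights(),
                rng_seed: int = 0) -> LossReport:
    if a_d is None:
        a_d = np.zeros(np.atleast_1d(np.asarray(a_s)).shape)
    _, report = critic_loss_t(critic, generator, x_real_s, a_s, x_real_t,
                              a_t_real, a_d, np.random.default_rng(rng_seed),
                              weights)
    return report


def generator_loss_t(critic, generator, x, a_s, a_d,
                     weights: LossWeights = LossWeights()):
    """Generator objective (adversarial + weighted cycle term)."""
    xb = _as_batch(x)
    a_s = np.atleast_1d(np.asarray(a_s, dtype=np.float64))
    a_d = np.atleast_1d(np.asarray(a_d, dtype=np.float64))
    xt = Tensor(xb)
    _, x_fwd = generator.synth_t(xt, a_d)
    adv = -critic.forward_t(x_fwd, a_s + a_d).mean()
    cyc = cycle_loss_t(generator, xb, a_d, x_fwd=x_fwd)
    total = adv + weights.cc * cyc
    report = LossReport(generator_adv=float(adv.item()),
                        cycle=float(cyc.item()),
                        generator_total=float(total.item()),
                        lambda_gp=weights.gp, lambda_cc=weights.cc)
    return total, report


def generator_loss(critic, generator, x, a_s, a_d,
                   weights: LossWeights = LossWeights()) -> LossReport:
    _, report = generator_loss_t(critic, generator, x, a_s, a_d, weights)
    return report
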