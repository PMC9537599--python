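"""Analytic identities of the adversarial, penalty and cycle objectives."""

import numpy as np
import pytest

from cardiosynth.nn import Tensor
from cardiosynth.objectives import (LossWeights, critic_loss, critic_loss_t,
                                    cycle_loss, generator_loss,
                                    gradient_penalty, interpolate)


class ConstantCritic:
    """D(x, a) = c for every input: zero input gradient."""

    def __init__(self, c=0.0):
        self.c = c

    def forward_t(self, x, a):
        return Tensor(np.full(x.shape[0], self.c, dtype=np.float32)) \
            + 0.0 * x.sum()


class LinearCritic:
    """D(x, a) = <w, x>: input gradient is w everywhere."""

    def __init__(self, w):
        self.w = Tensor(np.asarray(w, dtype=np.float64), requires_grad=True)

    def forward_t(self, x, a):
        n = x.shape[0]
        flat = x.reshape(n, int(np.prod(x.shape[1:])))
        return (flat @ self.w.reshape(-1, 1)).reshape(n)


class IdentityGenerator:
    def synth_t(self, x, a_d):
        return Tensor(np.zeros_like(x.data)), x


class ConstantShiftGenerator:
    """Adds a fixed offset regardless of the gap sign (breaks the cycle)."""

    def __init__(self, shift=0.1):
        self.shift = shift

    def synth_t(self, x, a_d):
        return (Tensor(np.full_like(x.data, self.shift)),
                x + np.float32(self.shift))


RNG = np.random.default_rng(0)
X_REAL = RNG.uniform(0, 1, (3, 1, 2, 2)).astype(np.float32)
X_GEN = RNG.uniform(0, 1, (3, 1, 2, 2)).astype(np.float32)
AGES = np.array([50.0, 60.0, 70.0])


class TestGradientPenalty:
    def test_constant_critic_gives_unit_penalty(self):
        pen = gradient_penalty(ConstantCritic(), X_REAL, X_GEN, AGES, 0)
        assert pen == pytest.approx(1.0, abs=1e-5)

    def test_unit_norm_linear_critic_gives_zero(self):
        w = np.zeros(4)
        w[2] = 1.0
        pen = gradient_penalty(LinearCritic(w), X_REAL, X_GEN, AGES, 1)
        assert pen == pytest.approx(0.0, abs=1e-5)

    def test_norm_three_linear_critic_gives_four(self):
        w = np.array([3.0, 0.0, 0.0, 0.0])
        pen = gradient_penalty(LinearCritic(w), X_REAL, X_GEN, AGES, 2)
        assert pen == pytest.approx(4.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_difference_oracle_on_random_small_critics(
            self, seed):
        """Penalty value agrees with a finite-difference estimate of the
        interpolate-point gradient norm on 4-pixel images."""
        rng = np.random.default_rng(seed)
        w = rng.normal(size=4)
        critic = LinearCritic(w)
        x_hat = interpolate(X_REAL, X_GEN, np.random.default_rng(seed))
        # finite-difference gradient of D at each interpolate
        eps = 1e-5
        pens = []
        for i in range(len(x_hat)):
            g = np.zeros(4)
            flat = x_hat[i].reshape(-1).astype(np.float64)
            for j in range(4):
                xp, xm = flat.copy(), flat.copy()
                xp[j] += eps
                xm[j] -= eps
                sp = float(xp @ w)
                sm = float(xm @ w)
                g[j] = (sp - sm) / (2 * eps)
            pens.append((np.linalg.norm(g) - 1.0) ** 2)
        expected = float(np.mean(pens))
        got = gradient_penalty(critic, X_REAL, X_GEN, AGES, seed)
        assert got == pytest.approx(expected, rel=1e-4)

    def test_interpolates_lie_between_endpoints(self):
        x_hat = interpolate(X_REAL, X_GEN, np.random.default_rng(3))
        lo = np.minimum(X_REAL, X_GEN)
        hi = np.maximum(X_REAL, X_GEN)
        assert np.all(x_hat >= lo - 1e-7) and np.all(x_hat <= hi + 1e-7)


class TestCriticLoss:
    def test_constant_critic_default_weights_gives_ten(self):
        rep = critic_loss(ConstantCritic(), IdentityGenerator(), X_REAL,
                          AGES, X_REAL, AGES, np.zeros(3))
        assert rep.critic_total == pytest.approx(10.0, abs=1e-4)

    def test_identity_generator_identical_batches_zero_core_zero_gp(self):
        w = np.zeros(4)
        w[0] = 1.0
        rep = critic_loss(LinearCritic(w), IdentityGenerator(), X_REAL,
                          AGES, X_REAL, AGES, np.zeros(3))
        assert rep.critic_core == pytest.approx(0.0, abs=1e-6)
        assert rep.gp == pytest.approx(0.0, abs=1e-6)

    def test_hand_arithmetic_on_one_pixel_images(self):
        """Brute-force check with scalar 'images' and a linear critic."""
        w = np.array([2.0])
        xs = np.array([[[[0.3]]], [[[0.7]]]], dtype=np.float32)
        xr = np.array([[[[0.5]]], [[[0.1]]]], dtype=np.float32)
        ages = np.array([50.0, 60.0])
        rep = critic_loss(LinearCritic(w), IdentityGenerator(), xs, ages,
                          xr, ages, np.zeros(2), rng_seed=0)
        core = 2.0 * (0.3 + 0.7) / 2 - 2.0 * (0.5 + 0.1) / 2
        gp = (2.0 - 1.0) ** 2          # |grad| = 2 at any interpolate
        assert rep.critic_core == pytest.approx(core, rel=1e-5)
        assert rep.gp == pytest.approx(gp, rel=1e-5)
        assert rep.critic_total == pytest.approx(core + 10 * gp, rel=1e-5)

    def test_mismatched_batches_rejected(self):
        with pytest.raises(ValueError, match="batch"):
            critic_loss(ConstantCritic(), IdentityGenerator(), X_REAL, AGES,
                        X_REAL[:2], AGES[:2], np.zeros(3))

    def test_zero_gp_weight_recovers_unpenalized_estimate(self):
        w = np.array([1.5, -0.5, 0.25, 1.0])
        weights = LossWeights(gp=0.0, cc=1.0)
        rep = critic_loss(LinearCritic(w), IdentityGenerator(), X_REAL, AGES,
                          X_GEN, AGES, np.zeros(3), weights=weights)
        assert rep.critic_total == pytest.approx(rep.critic_core, rel=1e-6)


class TestCycleLoss:
    def test_identity_generator_gives_zero(self):
        x = RNG.uniform(0, 1, (2, 1, 4, 4)).astype(np.float32)
        assert cycle_loss(IdentityGenerator(), x, np.array([10.0, -5.0])) \
            == 0.0

    def test_constant_shift_accumulates_twice(self):
        """A generator adding +0.1 regardless of gap sign reconstructs
        x + 0.2, so the L1 cycle loss is exactly 0.2 (no clipping active)."""
        x = np.full((1, 1, 2, 2), 0.5, dtype=np.float32)
        loss = cycle_loss(ConstantShiftGenerator(0.1), x, np.array([15.0]))
        assert loss == pytest.approx(0.2, rel=1e-6)


class TestGeneratorLoss:
    def test_all_terms_vanish_for_constant_critic_and_identity(self):
        weights = LossWeights(gp=10.0, cc=0.0)
        rep = generator_loss(ConstantCritic(), IdentityGenerator(), X_REAL,
                             AGES, np.zeros(3), weights)
        assert rep.generator_total == pytest.approx(0.0, abs=1e-7)
        rep2 = generator_loss(ConstantCritic(), IdentityGenerator(), X_REAL,
                              AGES, np.zeros(3), LossWeights())
        assert rep2.generator_total == pytest.approx(0.0, abs=1e-7)

    def test_total_is_adversarial_plus_weighted_cycle(self, toy_nets):
        G, D, _ = toy_nets
        x = RNG.uniform(0, 1, (2, 1, 32, 32)).astype(np.float32)
        weights = LossWeights(gp=10.0, cc=2.5)
        rep = generator_loss(D, G, x, np.array([50.0, 60.0]),
                             np.array([10.0, -10.0]), weights)
        assert rep.generator_total == pytest.approx(
            rep.generator_adv + 2.5 * rep.cycle, rel=1e-6)


def test_losses_finite_for_many_random_initializations():
    """All loss components stay finite across random small critics and
    random image batches."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        critic = LinearCritic(rng.normal(size=4))
        x_s = rng.uniform(0, 1, (2, 1, 2, 2)).astype(np.float32)
        x_r = rng.uniform(0, 1, (2, 1, 2, 2)).astype(np.float32)
        ages = rng.uniform(45, 82, 2)
        total, rep = critic_loss_t(critic, IdentityGenerator(), x_s, ages,
                                   x_r, ages, np.zeros(2),
                                   np.random.default_rng(seed))
        assert np.isfinite(total.item())
        assert np.isfinite(rep.gp) and rep.gp >= 0
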