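"""GAN objectives against brute-force per-sample oracles and analytic cases."""

import math

import numpy as np
import pytest

from ligandgen.latent_gan import (Critic, GanConfig, critic_loss,
                                  critic_scores, generator_loss,
                                  gradient_penalty, normalize_rows,
                                  supervised_contrastive_loss)
from ligandgen.nn import Tensor

RNG = np.random.default_rng(7)


class ConstCritic:
    """Stub critic returning constant scores on both heads."""

    def __init__(self, a, b):
        self.a, self.b = a, b

    def __call__(self, x, c):
        n = x.shape[0]
        return Tensor(np.full(n, float(self.a))), Tensor(np.full(n, float(self.b)))


class LinearStub:
    """Critic whose combined score has constant input gradient w."""

    def __init__(self, w_u, w_c):
        self.w_u = np.asarray(w_u, dtype=float)
        self.w_c = np.asarray(w_c, dtype=float)

    def __call__(self, x, c):
        wu = Tensor(self.w_u.reshape(-1, 1))
        wc = Tensor(self.w_c.reshape(-1, 1))
        return (x @ wu).reshape((-1,)), (x @ wc).reshape((-1,))


def supcon_brute(phi, labels, tau):
    n = len(labels)
    total = 0.0
    for i in range(n):
        pos = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not pos:
            continue
        acc = 0.0
        for j in pos:
            den = sum(math.exp(phi[i] @ phi[k] / tau)
                      for k in range(n) if k != i)
            acc += -math.log(math.exp(phi[i] @ phi[j] / tau) / den)
        total += acc / len(pos)
    return total


def generator_loss_brute(su, sc, mode):
    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))
    if mode == "wasserstein":
        return (-0.5 * sum(su) / len(su)) + (-0.5 * sum(sc) / len(sc))
    return (-0.5 * sum(math.log(sig(v)) for v in su) / len(su)
            - 0.5 * sum(math.log(sig(v)) for v in sc) / len(sc))


class TestSupCon:
    def test_symmetric_four_sample_batch(self):
        phi = Tensor(np.array([[1., 0.], [1., 0.], [0., 1.], [0., 1.]]))
        val = supervised_contrastive_loss(phi, np.array([0, 0, 1, 1]), 1.0)
        assert val.item() == pytest.approx(4 * math.log(1 + 2 / math.e), abs=1e-6)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_single_label_identical_embeddings(self, n):
        phi = Tensor(np.tile([[0.6, 0.8]], (n, 1)))
        val = supervised_contrastive_loss(phi, np.zeros(n), 0.37)
        assert val.item() == pytest.approx(n * math.log(n - 1) if n > 1 else 0,
                                           abs=1e-6)

    def test_all_labels_unique_gives_zero(self):
        phi = Tensor(np.eye(4))
        assert supervised_contrastive_loss(
            phi, np.arange(4), 1.0).item() == 0.0

    def test_brute_force_oracle_on_100_random_batches(self):
        for _ in range(100):
            n = int(RNG.integers(2, 12))
            x = RNG.normal(size=(n, 4))
            x /= np.linalg.norm(x, axis=1, keepdims=True)
            labels = RNG.integers(0, 3, n)
            tau = float(RNG.uniform(0.05, 2.0))
            got = supervised_contrastive_loss(Tensor(x), labels, tau).item()
            assert got == pytest.approx(supcon_brute(x, labels, tau), abs=1e-6)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            supervised_contrastive_loss(Tensor(np.eye(2)), np.zeros(2), 0.0)

    def test_normalize_rows_unit_norm(self):
        x = Tensor(RNG.normal(size=(6, 5)))
        norms = np.linalg.norm(normalize_rows(x).data, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)


class TestGeneratorLoss:
    def test_as_printed_at_half_sigmoid(self):
        l = generator_loss(Tensor(RNG.normal(size=(6, 2))),
                           Tensor(np.zeros((6, 2))), ConstCritic(0, 0),
                           "as_printed")
        assert l.item() == pytest.approx(math.log(2), abs=1e-9)

    def test_wasserstein_constant_scores(self):
        l = generator_loss(Tensor(RNG.normal(size=(6, 2))),
                           Tensor(np.zeros((6, 2))), ConstCritic(3, 1),
                           "wasserstein")
        assert l.item() == pytest.approx(-2.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["wasserstein", "as_printed"])
    def test_real_critic_matches_brute_force(self, mode):
        cfg = GanConfig.test_scale(seed=1)
        d = Critic(cfg, np.random.default_rng(1))
        for _ in range(100):
            n = int(RNG.integers(2, 10))
            x = Tensor(RNG.normal(size=(n, cfg.latent_dim)))
            c = Tensor(RNG.normal(size=(n, cfg.common_dim)))
            got = generator_loss(x, c, d, mode).item()
            su, sc = critic_scores(x.data, c.data, d)
            want = generator_loss_brute(su.astype(float), sc.astype(float), mode)
            assert got == pytest.approx(want, abs=1e-6)


class TestGradientPenalty:
    def test_linear_critic_norm5_analytic(self):
        """Combined gradient (3,0)+(0,4) has norm 5 -> penalty 16 lambda."""
        stub = LinearStub([3.0, 0.0], [0.0, 4.0])
        real = Tensor(RNG.normal(size=(8, 2)))
        fake = Tensor(RNG.normal(size=(8, 2)))
        gp = gradient_penalty(real, fake, Tensor(np.zeros((8, 2))), stub,
                              7.0, np.random.default_rng(0))
        assert gp.item() == pytest.approx(7.0 * 16.0, abs=1e-6)

    def test_unit_gradient_gives_zero(self):
        stub = LinearStub([1.0, 0.0], [0.0, 0.0])
        real = Tensor(RNG.normal(size=(8, 2)))
        fake = Tensor(RNG.normal(size=(8, 2)))
        gp = gradient_penalty(real, fake, Tensor(np.zeros((8, 2))), stub,
                              10.0, np.random.default_rng(0))
        assert gp.item() == pytest.approx(0.0, abs=1e-6)

    def test_nonnegative_for_real_critic(self):
        cfg = GanConfig.test_scale(seed=2)
        d = Critic(cfg, np.random.default_rng(2))
        real = Tensor(RNG.normal(size=(16, cfg.latent_dim)))
        fake = Tensor(RNG.normal(size=(16, cfg.latent_dim)))
        c = Tensor(RNG.normal(size=(16, cfg.common_dim)))
        assert gradient_penalty(real, fake, c, d, 10.0,
                                np.random.default_rng(3)).item() >= 0.0

    def test_mismatched_batches_raise(self):
        with pytest.raises(ValueError):
            gradient_penalty(Tensor(np.zeros((4, 2))), Tensor(np.zeros((5, 2))),
                             Tensor(np.zeros((4, 2))), ConstCritic(0, 0), 1.0,
                             np.random.default_rng(0))


class TestCriticLoss:
    def test_constant_stub_analytic(self):
        class TwoValueCritic:
            def __init__(self):
                self.calls = 0

            def __call__(self, x, c):
                # first call sees the real batch, second the fake batch
                v = 2.0 if self.calls == 0 else 0.0
                self.calls += 1
                n = x.shape[0]
                return Tensor(np.full(n, v)), Tensor(np.full(n, v))

        d = TwoValueCritic()
        real = Tensor(RNG.normal(size=(6, 2)))
        fake = Tensor(RNG.normal(size=(6, 2)))
        cond = Tensor(np.zeros((6, 2)))
        # suppress the penalty with lambda 0: remaining terms are -2+0-2+0
        val = critic_loss(real, fake, cond, d, 0.0, np.random.default_rng(0))
        assert val.item() == pytest.approx(-4.0, abs=1e-9)

    def test_identical_distributions_near_zero(self):
        cfg = GanConfig.test_scale(seed=3)
        d = Critic(cfg, np.random.default_rng(3))
        x = Tensor(RNG.normal(size=(64, cfg.latent_dim)))
        c = Tensor(RNG.normal(size=(64, cfg.common_dim)))
        val = critic_loss(x, x, c, d, 0.0, np.random.default_rng(0))
        assert val.item() == pytest.approx(0.0, abs=1e-6)

    def test_brute_force_oracle(self):
        cfg = GanConfig.test_scale(seed=4)
        d = Critic(cfg, np.random.default_rng(4))
        for _ in range(100):
            n = int(RNG.integers(2, 10))
            real = RNG.normal(size=(n, cfg.latent_dim))
            fake = RNG.normal(size=(n, cfg.latent_dim))
            c = RNG.normal(size=(n, cfg.common_dim))
            got = critic_loss(Tensor(real), Tensor(fake), Tensor(c), d, 0.0,
                              np.random.default_rng(0)).item()
            ru, rc = critic_scores(real, c, d)
            fu, fc = critic_scores(fake, c, d)
            want = (-sum(ru) / n + sum(fu) / n - sum(rc) / n + sum(fc) / n)
            assert got == pytest.approx(float(want), abs=1e-6)


class TestCriticHeads:
    def test_condition_shuffle_moves_only_conditional_head(self):
        cfg = GanConfig.test_scale(seed=5)
        d = Critic(cfg, np.random.default_rng(5))
        x = RNG.normal(size=(8, cfg.latent_dim))
        c = RNG.normal(size=(8, cfg.common_dim))
        su1, sc1 = critic_scores(x, c, d)
        su2, sc2 = critic_scores(x, c[::-1].copy(), d)
        assert np.allclose(su1, su2)
        assert not np.allclose(sc1, sc2)

    def test_scores_finite(self):
        cfg = GanConfig.test_scale(seed=6)
        d = Critic(cfg, np.random.default_rng(6))
        su, sc = critic_scores(RNG.normal(size=(4, cfg.latent_dim)),
                               RNG.normal(size=(4, cfg.common_dim)), d)
        assert np.isfinite(su).all() and np.isfinite(sc).all()
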