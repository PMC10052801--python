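"""Conditional WGAN-GP over molecular latents, with supervised contrast.

The generator maps standard-normal noise concatenated with a protein
condition vector to a molecular latent. A critic with a shared trunk and
two heads scores (i) the latent alone — is it drawn from the encoder's
distribution over real molecules — and (ii) the latent paired with its
condition — does the molecule belong with that target. Training follows
the WGAN-GP recipe: several critic updates per generator update, with a
gradient penalty pulling the norm of the critic's input gradient towards 1
on real/fake interpolates.

The generator objective adds a supervised contrastive term: generated
latents for the same target are pulled together on the unit sphere (via the
L2-normalised final hidden layer of the generator) and different targets
pushed apart, with temperature tau.

Two generator-loss conventions are provided. ``wasserstein`` (default)
uses the critic scores directly, matching the WGAN-GP critic. The
``as_printed`` mode applies a sigmoid before the log so that the log-form
adversarial loss is well defined for an unbounded critic.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Linear, Module, Tensor, concat, no_grad, DTYPE
from .nn.tensor import backward as backward_, grad as tgrad


@dataclass
class GanConfig:
    noise_dim: int = 128
    common_dim: int = 512
    latent_dim: int = 512
    hidden_dim: int = 256
    lambda_scl: float = 1.0     # weight of the supervised contrastive term
    lambda_gp: float = 10.0     # gradient-penalty coefficient
    tau: float = 0.1            # contrastive temperature
    n_critic: int = 5
    batch_size: int = 64
    generator_loss_mode: str = "wasserstein"   # or "as_printed"
    lr: float = 1e-3
    lr_decay: bool = False     # drop lr to 0.3x / 0.1x at 60% / 85% of steps
    betas: tuple[float, float] = (0.5, 0.9)
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.generator_loss_mode not in ("wasserstein", "as_printed"):
            raise ValueError("unknown generator_loss_mode")

    @classmethod
    def test_scale(cls, **kw) -> "GanConfig":
        defaults = dict(noise_dim=16, common_dim=16, latent_dim=32, hidden_dim=64)
        defaults.update(kw)
        return cls(**defaults)


class ConditionProjector(Module):
    """Perception layer: protein feature -> common-space condition vector."""

    def __init__(self, feature_dim: int, common_dim: int, rng: np.random.Generator):
        self.layer = Linear(feature_dim, common_dim, rng)

    def __call__(self, p: Tensor) -> Tensor:
        return self.layer(p).tanh()

    def project(self, features: np.ndarray) -> np.ndarray:
        with no_grad():
            return self(Tensor(features.astype(DTYPE))).data.copy()


class Generator(Module):
    """MLP from [z, c] to a molecular latent; exposes its final hidden layer."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        d_in = cfg.noise_dim + cfg.common_dim
        self.fc1 = Linear(d_in, cfg.hidden_dim, rng)
        self.fc2 = Linear(cfg.hidden_dim, cfg.hidden_dim, rng)
        self.out = Linear(cfg.hidden_dim, cfg.latent_dim, rng)

    def hidden(self, z: Tensor, c: Tensor) -> Tensor:
        h = self.fc1(concat([z, c], axis=-1)).relu()
        return self.fc2(h).relu()

    def __call__(self, z: Tensor, c: Tensor) -> Tensor:
        return self.out(self.hidden(z, c))


class Critic(Module):
    """Shared trunk with an unconditional and a conditional head."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        self.trunk1 = Linear(cfg.latent_dim, cfg.hidden_dim, rng)
        self.trunk2 = Linear(cfg.hidden_dim, cfg.hidden_dim, rng)
        self.head_u = Linear(cfg.hidden_dim, 1, rng)
        self.cond1 = Linear(cfg.hidden_dim + cfg.common_dim, cfg.hidden_dim, rng)
        self.head_c = Linear(cfg.hidden_dim, 1, rng)

    def __call__(self, x: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        t = self.trunk2(self.trunk1(x).relu()).relu()
        s_u = self.head_u(t)
        s_c = self.head_c(self.cond1(concat([t, c], axis=-1)).relu())
        return s_u.reshape((-1,)), s_c.reshape((-1,))


def generate(z: np.ndarray, c: np.ndarray, g: Generator) -> np.ndarray:
    """Evaluation-mode generation S = G(z, c)."""
    with no_grad():
        return g(Tensor(z.astype(DTYPE)), Tensor(c.astype(DTYPE))).data.copy()


def sample_noise(n: int, noise_dim: int, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal((n, noise_dim)).astype(DTYPE)


def critic_scores(x: np.ndarray, c: np.ndarray, d: Critic) -> tuple[np.ndarray, np.ndarray]:
    with no_grad():
        s_u, s_c = d(Tensor(x.astype(DTYPE)), Tensor(c.astype(DTYPE)))
    return s_u.data.copy(), s_c.data.copy()


def generator_loss(fake: Tensor, conditions: Tensor, d: Critic,
                   mode: str = "wasserstein") -> Tensor:
    """Adversarial generator loss over a fake batch.

    ``wasserstein``: -1/2 E[D(x)] - 1/2 E[D(x, c)].
    ``as_printed``: -1/2 E[log s(D(x))] - 1/2 E[log s(D(x, c))] with a
    sigmoid squashing the critic scores into (0, 1).
    """
    s_u, s_c = d(fake, conditions)
    if not (np.isfinite(s_u.data).all() and np.isfinite(s_c.data).all()):
        raise FloatingPointError("non-finite critic output")
    if mode == "wasserstein":
        return -0.5 * s_u.mean() - 0.5 * s_c.mean()
    if mode == "as_printed":
        return -0.5 * s_u.sigmoid().log().mean() - 0.5 * s_c.sigmoid().log().mean()
    raise ValueError(f"unknown mode {mode!r}")


def supervised_contrastive_loss(phi: Tensor, labels: np.ndarray,
                                tau: float) -> Tensor:
    """Supervised contrastive loss over unit-norm projections ``phi``.

    For each anchor i with at least one same-label partner, averages
    -log[ exp(phi_i . phi_j / tau) / sum_{k != i} exp(phi_i . phi_k / tau) ]
    over the partners j, and sums over anchors. Anchors whose label is
    unique in the batch contribute zero.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = phi.shape[0]
    labels = np.asarray(labels)
    sim = (phi @ phi.swap_last_axes()) * (1.0 / tau)
    off = 1.0 - np.eye(n, dtype=phi.data.dtype)
    # log sum over k != i, via a masked, shifted logsumexp
    shift = Tensor(np.where(off > 0, sim.data, -np.inf).max(axis=1, keepdims=True))
    expm = (sim - shift).exp() * Tensor(off)
    log_den = expm.sum(axis=1, keepdims=True).log() + shift
    log_prob = sim - log_den           # (n, n): log softmax over k != i
    pos = ((labels[:, None] == labels[None, :]) * off.astype(bool)).astype(phi.data.dtype)
    counts = pos.sum(axis=1)
    weights = np.divide(1.0, counts, out=np.zeros_like(counts), where=counts > 0)
    per_anchor = (log_prob * Tensor(pos)).sum(axis=1) * Tensor(weights)
    return -per_anchor.sum()


def normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + eps).sqrt()
    return x / norm


def gradient_penalty(real: Tensor, fake: Tensor, conditions: Tensor,
                     d: Critic, lambda_gp: float,
                     rng: np.random.Generator) -> Tensor:
    """WGAN-GP penalty on the combined score D(x) + D(x, c) at interpolates."""
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have the same shape")
    eps = rng.uniform(0.0, 1.0, size=(real.shape[0], 1)).astype(real.data.dtype)
    x_hat = Tensor((eps * real.data + (1.0 - eps) * fake.data))
    x_hat.requires_grad = True
    s_u, s_c = d(x_hat, conditions)
    total = (s_u + s_c).sum()
    (gx,) = tgrad(total, [x_hat], create_graph=True)
    norm = ((gx * gx).sum(axis=1) + 1e-12).sqrt()
    return lambda_gp * ((norm - 1.0) ** 2).mean()


def critic_loss(real: Tensor, fake: Tensor, conditions: Tensor, d: Critic,
                lambda_gp: float, rng: np.random.Generator) -> Tensor:
    """Two-head Wasserstein critic loss plus the gradient penalty."""
    ru, rc = d(real, conditions)
    fu, fc = d(fake, conditions)
    w = -ru.mean() + fu.mean() - rc.mean() + fc.mean()
    return w + gradient_penalty(real, fake, conditions, d, lambda_gp, rng)


@dataclass
class GanTrainingResult:
    generator: Generator
    critic: Critic
    losses: dict[str, list[float]] = field(default_factory=dict)


def train_gan(latents: np.ndarray, conditions: np.ndarray, labels: np.ndarray,
              config: GanConfig, generator_steps: int,
              ) -> GanTrainingResult:
    """Alternating WGAN-GP training on encoded molecular latents.

    ``latents``: (N, latent_dim) real latent vectors; ``conditions``:
    (N, common_dim) matched condition vectors; ``labels``: length-N target
    identifiers used by the contrastive term and for label-stratified
    batches.
    """
    rng = np.random.default_rng(config.seed)
    labels = np.asarray(labels)
    unique_labels = np.unique(labels)
    lambda_scl = config.lambda_scl
    if lambda_scl > 0 and unique_labels.size < 2:
        warnings.warn("single-target corpus: supervised contrastive term disabled")
        lambda_scl = 0.0

    g = Generator(config, rng)
    d = Critic(config, rng)
    g_opt = Adam(g.parameters(), lr=config.lr, betas=config.betas)
    d_opt = Adam(d.parameters(), lr=config.lr, betas=config.betas)
    g_params, d_params = g.parameters(), d.parameters()

    by_label = {lab: np.flatnonzero(labels == lab) for lab in unique_labels}
    B = min(config.batch_size, len(latents))

    def stratified_batch() -> np.ndarray:
        # round-robin over labels keeps every anchor supplied with positives
        per = max(2, B // max(len(unique_labels), 1))
        idx = []
        for lab in unique_labels:
            pool = by_label[lab]
            idx.append(rng.choice(pool, size=min(per, len(pool)), replace=len(pool) < per))
        idx = np.concatenate(idx)[:B]
        return idx

    losses: dict[str, list[float]] = {k: [] for k in
                                      ("L_G1", "L_SCL", "L_G", "L_D", "GP")}
    milestones = ({int(generator_steps * 0.6): config.lr * 0.3,
                   int(generator_steps * 0.85): config.lr * 0.1}
                  if config.lr_decay else {})
    for step in range(generator_steps):
        if step in milestones:
            g_opt.lr = d_opt.lr = milestones[step]
        for _ in range(config.n_critic):
            idx = stratified_batch()
            real = Tensor(latents[idx].astype(DTYPE))
            cond = Tensor(conditions[idx].astype(DTYPE))
            z = Tensor(sample_noise(len(idx), config.noise_dim, rng))
            with no_grad():
                fake_data = g(z, cond).data
            fake = Tensor(fake_data)
            gp = gradient_penalty(real, fake, cond, d, config.lambda_gp, rng)
            ru, rc = d(real, cond)
            fu, fc = d(fake, cond)
            l_d = -ru.mean() + fu.mean() - rc.mean() + fc.mean() + gp
            backward_(l_d, d_params)
            d_opt.step()
            d_opt.zero_grad()
        losses["L_D"].append(l_d.item())
        losses["GP"].append(gp.item())

        idx = stratified_batch()
        cond = Tensor(conditions[idx].astype(DTYPE))
        z = Tensor(sample_noise(len(idx), config.noise_dim, rng))
        hidden = g.hidden(z, cond)
        fake = g.out(hidden)
        l_g1 = generator_loss(fake, cond, d, config.generator_loss_mode)
        if lambda_scl > 0:
            phi = normalize_rows(hidden)
            l_scl = supervised_contrastive_loss(phi, labels[idx], config.tau)
        else:
            l_scl = Tensor(np.zeros(()))
        l_g = l_g1 + lambda_scl * l_scl
        backward_(l_g, g_params)
        g_opt.step()
        g_opt.zero_grad()
        losses["L_G1"].append(l_g1.item())
        losses["L_SCL"].append(float(l_scl.data))
        losses["L_G"].append(l_g.item())
    return GanTrainingResult(generator=g, critic=d, losses=losses)
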