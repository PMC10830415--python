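"""Wasserstein GAN with gradient penalty for one-hot DNA generation.

Architecture (defaults in :class:`GanConfig`):

* Generator: noise(128) -> dense(seq_len x channels = 64,000 units, ELU) ->
  reshape(seq_len, channels) -> five residual convolution blocks (ReLU then
  width-5, length-preserving convolution with ``channels`` filters, additive
  skip) -> width-1 convolution to 4 channels -> position-wise softmax.
  Output is (seq_len, 4) with rows summing to 1.
* Critic: one-hot input -> width-1 convolution with ``channels`` filters ->
  the same five-block tower -> flatten -> dense to a single unbounded unit.

Training follows the WGAN-GP recipe: per generator update,
``disc_iters_per_gen`` (default 10) critic updates, each penalized by
lambda * (||grad_xhat D(xhat)|| - 1)^2 on uniform real/fake interpolates;
Adam with learning rate 1e-4, beta1 0.5, beta2 0.9.  Full-scale runs on
genomic training sets are out of desk scope; the module is sized so smoke
runs on synthetic motif-implanted fixtures finish in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence as TypingSequence

import numpy as np

from .autodiff import Adam, Tensor, conv1d, elu, grad, relu, softmax
from .seqcore import Sequence, ValidationError, decode

__all__ = [
    "GanConfig",
    "Generator",
    "Critic",
    "build_generator",
    "build_discriminator",
    "train_wgan_gp",
    "sample_sequences",
    "layer_inventory",
]


@dataclass(frozen=True)
class GanConfig:
    seq_len: int = 500
    channels: int = 128
    noise_dim: int = 128
    tower_blocks: int = 5
    kernel: int = 5
    disc_iters_per_gen: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.9
    gp_lambda: float = 10.0

    def __post_init__(self) -> None:
        if min(self.seq_len, self.channels, self.noise_dim, self.batch_size) < 1:
            raise ValidationError("all GAN dimensions must be positive")
        if self.tower_blocks < 1 or self.kernel < 1:
            raise ValidationError("tower_blocks and kernel must be positive")

    @property
    def dense_units(self) -> int:
        return self.seq_len * self.channels


def smoke_config(**overrides) -> GanConfig:
    """Desk-scale configuration for tests and examples (same layer plan)."""
    defaults = dict(
        seq_len=64, channels=16, noise_dim=16, batch_size=32, learning_rate=1e-3
    )
    defaults.update(overrides)
    return GanConfig(**defaults)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class _Tower:
    """Shared residual convolution tower (ReLU -> width-k conv, additive skip)."""

    def __init__(self, config: GanConfig, rng: np.random.Generator) -> None:
        k, c = config.kernel, config.channels
        self.blocks = [
            (_glorot(rng, (k * c, c)), Tensor(np.zeros(c), requires_grad=True))
            for _ in range(config.tower_blocks)
        ]
        self.kernel = k

    def __call__(self, h: Tensor) -> Tensor:
        for w, b in self.blocks:
            h = h + conv1d(relu(h), w, b, self.kernel)
        return h

    @property
    def params(self) -> list[Tensor]:
        return [t for pair in self.blocks for t in pair]


class Generator:
    def __init__(self, config: GanConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        self.dense_w = _glorot(rng, (config.noise_dim, config.dense_units))
        self.dense_b = Tensor(np.zeros(config.dense_units), requires_grad=True)
        self.tower = _Tower(config, rng)
        self.out_w = _glorot(rng, (c, 4))
        self.out_b = Tensor(np.zeros(4), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.dense_w, self.dense_b, *self.tower.params, self.out_w, self.out_b]

    def __call__(self, noise: Tensor) -> Tensor:
        cfg = self.config
        n = noise.shape[0]
        h = elu(noise @ self.dense_w + self.dense_b.reshape(1, -1).broadcast_to(
            (n, cfg.dense_units)
        ))
        h = h.reshape(n, cfg.seq_len, cfg.channels)
        h = self.tower(h)
        h = conv1d(h, self.out_w.reshape(1 * cfg.channels, 4), self.out_b, kernel=1)
        return softmax(h)


class Critic:
    def __init__(self, config: GanConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        self.in_w = _glorot(rng, (4, c))
        self.in_b = Tensor(np.zeros(c), requires_grad=True)
        self.tower = _Tower(config, rng)
        self.dense_w = _glorot(rng, (config.seq_len * c, 1))
        self.dense_b = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.in_w, self.in_b, *self.tower.params, self.dense_w, self.dense_b]

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        n = x.shape[0]
        h = conv1d(x, self.in_w, self.in_b, kernel=1)
        h = self.tower(h)
        flat = h.reshape(n, cfg.seq_len * cfg.channels)
        return flat @ self.dense_w + self.dense_b.reshape(1, 1).broadcast_to((n, 1))


def build_generator(config: GanConfig | None = None, seed: int = 0) -> Generator:
    return Generator(config or GanConfig(), seed=seed)


def build_discriminator(config: GanConfig | None = None, seed: int = 0) -> Critic:
    return Critic(config or GanConfig(), seed=seed)


def layer_inventory(config: GanConfig | None = None) -> dict[str, list[dict]]:
    """Programmatic layer-by-layer description of both networks."""
    cfg = config or GanConfig()
    generator = [
        {"layer": "input_noise", "size": cfg.noise_dim},
        {"layer": "dense", "units": cfg.dense_units, "activation": "elu"},
        {"layer": "reshape", "shape": (cfg.seq_len, cfg.channels)},
        *[
            {
                "layer": "conv_block",
                "activation": "relu",
                "filters": cfg.channels,
                "kernel": cfg.kernel,
                "skip": "additive",
            }
            for _ in range(cfg.tower_blocks)
        ],
        {"layer": "conv1d", "filters": 4, "kernel": 1},
        {"layer": "softmax", "axis": "position-wise"},
    ]
    critic = [
        {"layer": "input_onehot", "shape": (cfg.seq_len, 4)},
        {"layer": "conv1d", "filters": cfg.channels, "kernel": 1},
        *[
            {
                "layer": "conv_block",
                "activation": "relu",
                "filters": cfg.channels,
                "kernel": cfg.kernel,
                "skip": "additive",
            }
            for _ in range(cfg.tower_blocks)
        ],
        {"layer": "flatten"},
        {"layer": "dense", "units": 1, "activation": None},
    ]
    return {"generator": generator, "discriminator": critic}


def gradient_penalty(
    critic: Critic, real: np.ndarray, fake: np.ndarray, rng: np.random.Generator
) -> Tensor:
    """lambda-free penalty term mean((||grad_xhat D(xhat)|| - 1)^2)."""
    eps = rng.random((real.shape[0], 1, 1))
    x_hat = Tensor(eps * real + (1 - eps) * fake, requires_grad=True)
    d_hat = critic(x_hat)
    (g_x,) = grad(d_hat.sum(), [x_hat])
    norms = (g_x**2.0).sum(axis=(1, 2)) ** 0.5
    return ((norms - 1.0) ** 2.0).mean()


def train_wgan_gp(
    real_onehot: np.ndarray,
    config: GanConfig,
    n_generator_iters: int,
    seed: int,
) -> tuple[Generator, dict[str, list[float]]]:
    """Train the generator against the critic on one-hot real sequences.

    ``real_onehot`` is (n, seq_len, 4).  Losses are recorded per update;
    training aborts with a diagnostic on any non-finite loss.  Fully seeded:
    weight init, noise, batch selection and interpolates all derive from
    ``seed``.
    """
    real_onehot = np.asarray(real_onehot, dtype=np.float64)
    if real_onehot.ndim != 3 or real_onehot.shape[2] != 4:
        raise ValidationError("real set must be (n, seq_len, 4) one-hot")
    if real_onehot.shape[1] != config.seq_len:
        raise ValidationError("real set length does not match config.seq_len")
    if real_onehot.shape[0] < config.batch_size:
        raise ValidationError("need at least one full batch of real sequences")

    rng = np.random.default_rng(seed)
    gen = Generator(config, seed=int(rng.integers(2**31)))
    critic = Critic(config, seed=int(rng.integers(2**31)))
    opt_g = Adam(gen.params, config.learning_rate, config.beta1, config.beta2)
    opt_d = Adam(critic.params, config.learning_rate, config.beta1, config.beta2)
    history: dict[str, list[float]] = {"critic_loss": [], "gradient_penalty": [], "generator_loss": []}

    def noise_batch() -> Tensor:
        return Tensor(rng.normal(0, 1, (config.batch_size, config.noise_dim)))

    for it in range(n_generator_iters):
        for _ in range(config.disc_iters_per_gen):
            idx = rng.choice(real_onehot.shape[0], config.batch_size, replace=False)
            real = real_onehot[idx]
            fake = gen(noise_batch()).data  # detached for the critic update
            d_real = critic(Tensor(real)).mean()
            d_fake = critic(Tensor(fake)).mean()
            gp = gradient_penalty(critic, real, fake, rng)
            loss_d = d_fake - d_real + config.gp_lambda * gp
            if not np.isfinite(loss_d.data):
                raise RuntimeError(
                    f"non-finite critic loss at generator iter {it}: "
                    f"W-term={float((d_fake - d_real).data):.4g} gp={float(gp.data):.4g}"
                )
            opt_d.step(grad(loss_d, critic.params))
            history["critic_loss"].append(float(loss_d.data))
            history["gradient_penalty"].append(float(gp.data))
        loss_g = -critic(gen(noise_batch())).mean()
        if not np.isfinite(loss_g.data):
            raise RuntimeError(f"non-finite generator loss at iter {it}")
        opt_g.step(grad(loss_g, gen.params))
        history["generator_loss"].append(float(loss_g.data))
    return gen, history


def sample_sequences(
    generator: Generator, n_batches: int, seed: int
) -> list[Sequence]:
    """Decode generator output to sequences: per-position argmax over the
    softmax probabilities (ties resolve to the lowest base index, A<C<G<T).

    Returns ``n_batches * batch_size`` sequences.
    """
    if n_batches < 1:
        raise ValidationError("n_batches must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = generator.config
    out: list[Sequence] = []
    for b in range(n_batches):
        z = Tensor(rng.normal(0, 1, (cfg.batch_size, cfg.noise_dim)))
        probs = generator(z).data
        codes = probs.argmax(axis=2)
        for i in range(cfg.batch_size):
            out.append(
                Sequence(id=f"gan_{b * cfg.batch_size + i}", residues=decode(codes[i]))
            )
    return out
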