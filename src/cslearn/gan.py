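"""Latent-to-image generator and discriminator with cycle consistency.

The generator G maps a d-dimensional latent vector to an image and is
trained adversarially against a discriminator D while the embedder E and
the prototypes stay frozen. G's input is the embedding E(X) of a real
training image — not Gaussian noise — and a cycle-consistency term keeps
E(G(E(X))) close to E(X), so G learns to invert the embedder on the data
manifold. That inversion is what later turns perturbed latent anchors into
plausible proxy images.

Losses are the original non-saturating GAN pair: D minimizes
-log s(D(real)) - log(1 - s(D(fake))); G minimizes -log s(D(G(.)))
plus lam * cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor
from .embedding import EmbeddingNetwork
from .losses import cycle_loss

__all__ = [
    "Generator",
    "Discriminator",
    "GanConfig",
    "build_generator",
    "build_discriminator",
    "discriminator_step_loss",
    "generator_step_loss",
    "train_gan",
]


@dataclass
class GanConfig:
    lam: float = 1.0  # cycle-consistency weight
    lr: float = 1e-4
    n_iterations: int = 2000
    batch_size: int = 16
    n_layers: int = 4  # per network; 9 matches the full-scale setting
    width: int = 8  # base channel count of G and D
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


class Generator(nn.Module):
    """Linear seed + transposed-convolution stack, sigmoid head to [0,1]."""

    def __init__(self, latent_dim: int, image_size: int, rng: np.random.Generator, channels: int = 1, n_layers: int = 4, width: int = 16):
        super().__init__()
        n_up = max(n_layers - 1, 1)
        if image_size % (2**n_up):
            raise ValueError(f"image_size {image_size} not divisible by 2^{n_up}")
        self.base = image_size // (2**n_up)
        self.c0 = width * (2 ** (n_up - 1))
        self.latent_dim = latent_dim
        self.fc = nn.Linear(latent_dim, self.c0 * self.base * self.base, rng)
        ups = []
        c = self.c0
        for i in range(n_up):
            c_out = channels if i == n_up - 1 else c // 2
            ups.append(nn.ConvTranspose2d(c, c_out, 4, rng, stride=2, pad=1))
            c = c_out
        self.ups = ups

    def forward(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        h = self.fc(z).relu().reshape(n, self.c0, self.base, self.base)
        for i, up in enumerate(self.ups):
            h = up(h)
            if i < len(self.ups) - 1:
                h = h.relu()
        return h.sigmoid()

    def generate(self, latents: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Evaluation-mode image synthesis for a latent stack (n, d)."""
        from .autodiff import no_grad

        latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
        out = []
        with no_grad():
            for start in range(0, len(latents), batch_size):
                out.append(self.forward(Tensor(latents[start : start + batch_size])).data)
        return np.concatenate(out, axis=0)


class Discriminator(nn.Module):
    """Strided convolution stack to a single realness logit per image."""

    def __init__(self, image_size: int, rng: np.random.Generator, channels: int = 1, n_layers: int = 4, width: int = 16):
        super().__init__()
        self.channels = channels
        n_down = max(n_layers - 1, 1)
        if image_size % (2**n_down):
            raise ValueError(f"image_size {image_size} not divisible by 2^{n_down}")
        convs = []
        c = channels
        for i in range(n_down):
            c_out = width * (2**i)
            convs.append(nn.Conv2d(c, c_out, 4, rng, stride=2, pad=1))
            c = c_out
        self.convs = convs
        feat = c * (image_size // (2**n_down)) ** 2
        self.fc = nn.Linear(feat, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        h = h.reshape(h.shape[0], int(np.prod(h.shape[1:])))
        return self.fc(h).reshape(h.shape[0])


def build_generator(latent_dim: int, image_size: int, seed=0, channels: int = 1, n_layers: int = 4, width: int = 8) -> Generator:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Generator(latent_dim, image_size, rng, channels=channels, n_layers=n_layers, width=width)


def build_discriminator(image_size: int, seed=0, channels: int = 1, n_layers: int = 4, width: int = 8) -> Discriminator:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Discriminator(image_size, rng, channels=channels, n_layers=n_layers, width=width)


def _as_image_tensor(images, channels: int) -> Tensor:
    if isinstance(images, Tensor):
        return images
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[:, None]
        if channels == 3:
            arr = np.repeat(arr, 3, axis=1)
    return Tensor(arr)


def discriminator_step_loss(disc: Discriminator, real_images, fake_images) -> Tensor:
    """Binary adversarial loss: -log s(D(real)) - log(1 - s(D(fake)))."""
    channels = getattr(disc, "channels", 1)
    real = _as_image_tensor(real_images, channels)
    fake = _as_image_tensor(fake_images, channels)
    if real.shape[0] == 0 or fake.shape[0] == 0:
        raise ValueError("empty batch")
    logit_real = disc(real)
    logit_fake = disc(fake)
    # -log s(x) = -logsigmoid(x); -log(1 - s(x)) = -logsigmoid(-x)
    return (-(logit_real.log_sigmoid())).mean() + (-((-logit_fake).log_sigmoid())).mean()


def generator_step_loss(
    gen: Generator,
    disc: Discriminator,
    embedder: EmbeddingNetwork,
    real_images: np.ndarray,
    lam: float = 1.0,
    latents: np.ndarray | None = None,
) -> tuple[Tensor, float, float]:
    """Non-saturating adversarial term plus lam * cycle consistency.

    The embedder must be frozen: its parameters take no gradient, but the
    chain E(G(E(X))) still propagates gradient through E's ops into G.
    ``latents`` may carry precomputed E(real_images) (the embedder is frozen,
    so they never change). Returns (total loss tensor, adversarial value,
    cycle value).
    """
    if not embedder.net.is_frozen():
        raise RuntimeError("embedder must be frozen during GAN training")
    embedder.net.eval()
    if latents is None:
        latents = embedder.embed_numpy(np.asarray(real_images, dtype=np.float64))
    f = Tensor(latents)  # generator input: the fixed embedding of a real image
    fake = gen(f)
    adv = (-(disc(fake).log_sigmoid())).mean()
    f_cycle = embedder.net(fake)  # gradient flows through E's ops into G
    cyc = cycle_loss(Tensor(f.data), f_cycle)
    total = adv + lam * cyc if lam else adv
    return total, adv.item(), cyc.item()


@dataclass
class GanTrainLog:
    iteration: list[int] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    g_adv: list[float] = field(default_factory=list)
    g_cycle: list[float] = field(default_factory=list)

    def as_rows(self):
        return list(zip(self.iteration, self.d_loss, self.g_adv, self.g_cycle))


def train_gan(
    embedder: EmbeddingNetwork,
    prototypes,
    train_images: np.ndarray,
    config: GanConfig,
) -> tuple[Generator, Discriminator, GanTrainLog]:
    """Alternating D/G optimization under a frozen embedder.

    One discriminator step then one generator step per iteration, Adam on
    both. The embedder and prototype matrix are asserted bit-identical
    before/after. Aborts if the generator loss goes non-finite.
    """
    rng = np.random.default_rng(config.seed)
    e_sum_before = embedder.checksum()
    m_before = prototypes.matrix.copy()
    was_frozen = embedder.net.is_frozen()
    embedder.net.freeze()

    gen = build_generator(
        embedder.latent_dim, embedder.image_size, rng,
        channels=embedder.channels, n_layers=config.n_layers, width=config.width,
    )
    disc = build_discriminator(
        embedder.image_size, rng,
        channels=embedder.channels, n_layers=config.n_layers, width=config.width,
    )
    opt_d = nn.Adam(disc.parameters(), lr=config.lr)
    opt_g = nn.Adam(gen.parameters(), lr=config.lr)
    log = GanTrainLog()
    n = len(train_images)
    train_latents = embedder.embed_numpy(np.asarray(train_images, dtype=np.float64))
    for it in range(config.n_iterations):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        batch = train_images[idx]

        fake = gen.generate(train_latents[idx], batch_size=len(idx))
        d_total = discriminator_step_loss(disc, batch, fake)
        opt_d.zero_grad()
        d_total.backward()
        opt_d.step()

        g_total, g_adv, g_cyc = generator_step_loss(
            gen, disc, embedder, batch, config.lam, latents=train_latents[idx]
        )
        if not np.isfinite(g_total.item()):
            raise FloatingPointError(f"generator loss diverged at iteration {it}")
        opt_g.zero_grad()
        g_total.backward()
        opt_g.step()

        log.iteration.append(it)
        log.d_loss.append(d_total.item())
        log.g_adv.append(g_adv)
        log.g_cycle.append(g_cyc)

    if not was_frozen:
        embedder.net.unfreeze()
    if embedder.checksum() != e_sum_before or not np.array_equal(prototypes.matrix, m_before):
        raise RuntimeError("freezing contract violated: embedder or prototypes changed")
    return gen, disc, log
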