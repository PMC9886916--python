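"""Unknown-anchor generation by perturbation and rejection sampling.

An anchor candidate is the embedding of a training image plus a small
random offset delta (direction uniform on the unit sphere, norm uniform on
(0, delta_max]). A candidate is accepted with probability

    P = min( min_k ||f - m_k||_2 / r , 1 )

where r is a radius threshold exceeding the nearest-prototype distance of
at least a fraction q (default 70%) of the training samples. Candidates
close to a prototype — likely still a known-class point — are therefore
rarely kept, and the accepted set is biased toward the gaps between and
around the class clusters. Sampling repeats until the accepted count
matches the number of training images; each accepted anchor is paired with
the frozen generator's proxy image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingNetwork, PrototypeSet, nearest_prototype
from .gan import Generator

__all__ = [
    "RadiusThreshold",
    "AnchorSet",
    "compute_radius_threshold",
    "propose_anchor",
    "propose_anchor_batch",
    "acceptance_probability",
    "generate_anchor_set",
]


@dataclass(frozen=True)
class RadiusThreshold:
    """Latent-space radius r (unsquared L2 units) and its source quantile q."""

    r: float
    q: float

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("radius threshold must be positive")
        if not 0 < self.q <= 1:
            raise ValueError("quantile must lie in (0, 1]")


@dataclass
class AnchorSet:
    """Accepted anchors, their proxy images and full provenance."""

    anchors: np.ndarray  # (N, d)
    proxy_images: np.ndarray  # (N, C, H, W)
    source_index: np.ndarray  # (N,) index of the perturbed training sample
    deltas: np.ndarray  # (N, d) the perturbation that produced each anchor
    acceptance_rate: float
    radius: RadiusThreshold
    delta_max: float

    def __len__(self) -> int:
        return len(self.anchors)


def compute_radius_threshold(
    train_latents: np.ndarray, prototypes: PrototypeSet, q: float = 0.70
) -> RadiusThreshold:
    """Empirical q-quantile (higher convention) of nearest-prototype distances.

    Distances are unsquared L2. The "higher" order statistic — the smallest
    observed distance >= a fraction q of the sample — guarantees r is at
    least as large as q of the training distances.
    """
    train_latents = np.atleast_2d(np.asarray(train_latents, dtype=np.float64))
    if train_latents.size == 0:
        raise ValueError("cannot compute a radius from an empty training set")
    _, d2 = nearest_prototype(train_latents, prototypes)
    dist = np.sort(np.sqrt(d2))
    idx = max(int(np.ceil(q * dist.size)), 1) - 1
    return RadiusThreshold(r=float(dist[min(idx, dist.size - 1)]), q=q)


def _sample_deltas(n: int, d: int, delta_max: float, rng: np.random.Generator) -> np.ndarray:
    """n offsets: direction uniform on S^{d-1}, norm uniform on (0, delta_max]."""
    direction = rng.standard_normal((n, d))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    norm = (1.0 - rng.uniform(0.0, 1.0, size=(n, 1))) * delta_max  # (0, delta_max]
    return direction * norm


def propose_anchor(
    latent: np.ndarray, delta_max: float = 0.2, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One candidate f_init = latent + delta; returns (f_init, delta)."""
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    rng = rng or np.random.default_rng()
    latent = np.asarray(latent, dtype=np.float64)
    delta = _sample_deltas(1, latent.shape[-1], delta_max, rng)[0]
    return latent + delta, delta


def propose_anchor_batch(
    latents: np.ndarray, delta_max: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`propose_anchor` for a stack of latents."""
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
    deltas = _sample_deltas(len(latents), latents.shape[1], delta_max, rng)
    return latents + deltas, deltas


def acceptance_probability(
    f_init: np.ndarray, prototypes: PrototypeSet, r: float
) -> np.ndarray | float:
    """P = min(min_k ||f_init - m_k||_2 / r, 1); elementwise for batches."""
    if r <= 0:
        raise ValueError("radius threshold must be positive")
    single = np.asarray(f_init).ndim == 1
    _, d2 = nearest_prototype(np.atleast_2d(f_init), prototypes)
    p = np.minimum(np.sqrt(d2) / r, 1.0)
    return float(p[0]) if single else p


def generate_anchor_set(
    embedder: EmbeddingNetwork,
    generator: Generator,
    prototypes: PrototypeSet,
    train_images: np.ndarray,
    radius: RadiusThreshold | float,
    n_target: int | None = None,
    delta_max: float = 0.2,
    rng: np.random.Generator | int = 0,
    min_acceptance: float = 0.01,
) -> AnchorSet:
    """Rejection-sample anchors until ``n_target`` accepted, then render proxies.

    Each proposal perturbs the embedding of a uniformly drawn training
    image; acceptance follows :func:`acceptance_probability`. If fewer than
    ``min_acceptance`` of the trailing 10^4 proposals are accepted the run
    aborts — that signals r mis-scaled against delta_max.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if isinstance(radius, (int, float)):
        radius = RadiusThreshold(r=float(radius), q=0.70)
    n_train = len(train_images)
    if n_target is None:
        n_target = n_train  # paper setting: as many anchors as training images
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    train_latents = embedder.embed_numpy(np.asarray(train_images, dtype=np.float64))

    anchors, sources, deltas = [], [], []
    n_proposed = n_accepted = 0
    recent: list[bool] = []
    chunk = max(n_target, 256)
    while n_accepted < n_target:
        idx = rng.integers(0, n_train, size=chunk)
        cand, delta = propose_anchor_batch(train_latents[idx], delta_max, rng)
        p = acceptance_probability(cand, prototypes, radius.r)
        accept = rng.uniform(size=chunk) < p
        consumed = chunk
        for j in np.flatnonzero(accept):
            anchors.append(cand[j])
            sources.append(idx[j])
            deltas.append(delta[j])
            n_accepted += 1
            if n_accepted == n_target:
                consumed = j + 1  # proposals past the final acceptance don't count
                break
        n_proposed += consumed
        recent.extend(accept[:consumed].tolist())
        if len(recent) > 10_000:
            recent = recent[-10_000:]
        if len(recent) == 10_000 and np.mean(recent) < min_acceptance:
            raise RuntimeError(
                f"anchor acceptance rate {np.mean(recent):.4f} below {min_acceptance}; "
                "radius threshold r is likely mis-scaled relative to delta_max"
            )
    anchors = np.stack(anchors)
    proxies = generator.generate(anchors)
    return AnchorSet(
        anchors=anchors,
        proxy_images=proxies,
        source_index=np.array(sources, dtype=np.int64),
        deltas=np.stack(deltas),
        acceptance_rate=n_accepted / n_proposed,
        radius=radius,
        delta_max=delta_max,
    )
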