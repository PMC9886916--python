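"""Differentiable losses for centralized space learning.

Stage 1 (known-space initialization) combines three terms:

* distance-based cross entropy (DCE): softmax over negative scaled squared
  distances to the K prototypes, -log of the correct class's probability;
* prototype loss: squared distance of a sample to its class prototype
  (intra-class variance);
* separation loss: max_i -log ||m_i - mu||^2 — pushes whichever prototype
  sits closest to the center mu radially outward, vacating the center.

Stage 3 (centralized-space refinement) adds the cluster penalty, which
attracts proxy-image embeddings to mu via a (K+1)-way distance softmax over
{mu} union M. A ``literal`` mode evaluates an alternative ratio-of-
exponentials form of that penalty, which algebraically reduces to
-gamma * sum_i d(z, m_i); it is retained for auditability but is not a
usable clustering objective (unbounded below), hence not the default.

All functions accept single samples (d,) or batches (n, d) and return a
scalar tensor; batch reduction is the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, logsumexp
from .embedding import PrototypeSet, compute_center, squared_distance_matrix

__all__ = [
    "LossWeights",
    "dce_loss",
    "prototype_loss",
    "separation_loss",
    "ksi_loss",
    "cycle_loss",
    "cluster_penalty",
    "csr_loss",
]


@dataclass
class LossWeights:
    """Hyperparameters balancing the loss terms.

    gamma scales distances inside the softmax (assignment hardness); alpha1,
    beta1 weight the prototype and separation terms in stage 1; alpha2,
    beta2, theta do the same in stage 3 with theta on the cluster penalty;
    lam weights the cycle-consistency term in the GAN objective; epsilon is
    the log-clamp floor in the separation loss.
    """

    gamma: float = 1.0
    alpha1: float = 0.1
    beta1: float = 0.1
    alpha2: float = 0.1
    beta2: float = 0.01
    theta: float = 0.1
    lam: float = 1.0
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for name in ("alpha1", "beta1", "alpha2", "beta2", "theta", "lam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _as_batch(z) -> Tensor:
    z = Tensor.as_tensor(z)
    return z.reshape(1, z.shape[0]) if z.ndim == 1 else z


def _labels_to_rows(labels, prototypes: PrototypeSet, n: int) -> np.ndarray:
    labels = np.atleast_1d(np.asarray(labels))
    if labels.size == 1 and n > 1:
        labels = np.repeat(labels, n)
    id_to_row = {cid: i for i, cid in enumerate(prototypes.class_ids)}
    try:
        rows = np.array([id_to_row[int(l)] for l in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]} has no prototype") from exc
    return rows


def dce_loss(latents, labels, prototypes: PrototypeSet, gamma: float = 1.0) -> Tensor:
    """Distance-based cross entropy, mean over the batch.

    -log softmax_k(-gamma * ||z - m_k||^2); computed through a stable
    log-sum-exp so any finite distances give a finite loss.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    z = _as_batch(latents)
    rows = _labels_to_rows(labels, prototypes, z.shape[0])
    logits = squared_distance_matrix(z, prototypes.M) * (-gamma)
    nll = logsumexp(logits, axis=1) - logits[np.arange(z.shape[0]), rows]
    return nll.mean()


def prototype_loss(latents, labels, prototypes: PrototypeSet) -> Tensor:
    """Mean squared distance of each sample to its own class prototype."""
    z = _as_batch(latents)
    rows = _labels_to_rows(labels, prototypes, z.shape[0])
    diff = z - prototypes.M[rows]
    return (diff**2.0).sum(axis=1).mean()


def separation_loss(prototypes: PrototypeSet, epsilon: float = 1e-8) -> Tensor:
    """max_i -log max(||m_i - mu||^2, epsilon) with mu the prototype mean.

    The max targets the prototype currently nearest mu; the clamp keeps the
    loss finite if a prototype coincides with mu. Gradient reaches the
    argmax prototype directly and every prototype through mu.
    """
    if prototypes.n_classes < 2:
        raise ValueError("separation loss needs at least two prototypes")
    mu = compute_center(prototypes)
    d2 = ((prototypes.M - mu.reshape(1, prototypes.latent_dim)) ** 2.0).sum(axis=1)
    return (-(d2.maximum(epsilon).log())).max()


def ksi_loss(latents, labels, prototypes: PrototypeSet, weights: LossWeights) -> Tensor:
    """Stage-1 objective: DCE + alpha1 * prototype + beta1 * separation."""
    z = _as_batch(latents)
    if z.shape[0] == 0:
        raise ValueError("empty batch")
    total = dce_loss(z, labels, prototypes, weights.gamma)
    if weights.alpha1:
        total = total + weights.alpha1 * prototype_loss(z, labels, prototypes)
    if weights.beta1:
        total = total + weights.beta1 * separation_loss(prototypes, weights.epsilon)
    return total


def cycle_loss(original, reconstructed) -> Tensor:
    """Mean L2 norm (not squared) between latent and re-embedded latent."""
    f = _as_batch(original)
    f2 = _as_batch(reconstructed)
    if f.shape != f2.shape:
        raise ValueError(f"latent shape mismatch {f.shape} vs {f2.shape}")
    return ((f2 - f) ** 2.0).sum(axis=1).sqrt().mean()


def cluster_penalty(
    latents,
    prototypes: PrototypeSet,
    gamma: float = 1.0,
    mode: str = "softmax",
    center: Tensor | None = None,
) -> Tensor:
    """Attract anchor embeddings to the center mu.

    ``softmax`` (default): -log of the center's probability under a
    (K+1)-way distance softmax over {mu} union M — decreases as z approaches
    mu and moves away from every prototype. ``literal``: the
    alternative closed form -gamma * sum_i d(z, m_i), evaluated literally as
    the ratio of exponentials it came from.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if mode not in ("softmax", "literal"):
        raise ValueError(f"unknown cluster_penalty mode {mode!r}")
    z = _as_batch(latents)
    mu = compute_center(prototypes) if center is None else center
    d_mu = ((z - mu.reshape(1, z.shape[1])) ** 2.0).sum(axis=1, keepdims=True)
    d_m = squared_distance_matrix(z, prototypes.M)
    if mode == "softmax":
        logits = concatenate([d_mu, d_m], axis=1) * (-gamma)
        nll = logsumexp(logits, axis=1) - logits[np.arange(z.shape[0]), np.zeros(z.shape[0], dtype=int)]
        return nll.mean()
    # literal ratio: -log( e^{-g d_mu} / e^{-g (d_mu + sum_i d_m_i)} )
    log_num = -gamma * d_mu.reshape(z.shape[0])
    log_den = -gamma * (d_mu.reshape(z.shape[0]) + d_m.sum(axis=1))
    return (-(log_num - log_den)).mean()


def csr_loss(
    known_latents,
    labels,
    anchor_latents,
    prototypes: PrototypeSet,
    weights: LossWeights,
    cluster_mode: str = "softmax",
    cluster_sign: float = 1.0,
    cluster_grad_to_prototypes: bool = False,
) -> Tensor:
    """Stage-3 objective: DCE + alpha2*prototype + beta2*separation + theta*cluster.

    The cluster term is evaluated against a detached copy of M (and hence a
    detached mu) by default, so prototypes receive gradient only through the
    other three terms while the embedder is steered by all four;
    ``cluster_grad_to_prototypes=True`` lifts that stop. ``cluster_sign=-1``
    flips the term for the counter-centralized ablation.
    """
    z = _as_batch(known_latents)
    if z.shape[0] == 0:
        raise ValueError("empty known batch")
    total = dce_loss(z, labels, prototypes, weights.gamma)
    if weights.alpha2:
        total = total + weights.alpha2 * prototype_loss(z, labels, prototypes)
    if weights.beta2:
        total = total + weights.beta2 * separation_loss(prototypes, weights.epsilon)
    if weights.theta and anchor_latents is not None:
        za = _as_batch(anchor_latents)
        if za.shape[0]:
            target = prototypes if cluster_grad_to_prototypes else PrototypeSet(
                prototypes.M.detach(), class_ids=prototypes.class_ids
            )
            term = cluster_penalty(za, target, weights.gamma, mode=cluster_mode)
            total = total + (weights.theta * cluster_sign) * term
    return total
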