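"""Three-stage training pipeline and its configuration.

Stage 1 (known-space initialization) trains the embedder and prototypes
jointly on the DCE + prototype + separation objective, laying known classes
out on a hypersphere around the prototype mean mu. Stage 2 trains the
latent-to-image GAN under a frozen embedder, then rejection-samples the
unknown-anchor set. Stage 3 (centralized-space refinement) fine-tunes the
embedder with known batches plus anchor/proxy batches so proxy-image
embeddings collapse onto mu while known classes stay on their prototypes.

Variant modes reproduce the latent-layout ablations: ``csl`` (default),
``counter_centralized`` (cluster penalty sign-flipped, pushing unknowns
outward), ``random_push`` (cluster penalty replaced by a push away from the
nearest prototype) and ``init_only`` (stop after stage 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .anchor_gen import AnchorSet, compute_radius_threshold, generate_anchor_set
from .autodiff import Tensor
from .embedding import (
    EmbeddingNetwork,
    PrototypeSet,
    build_embedding_network,
    save_prototype_sidecar,
    squared_distance_matrix,
)
from .gan import Discriminator, GanConfig, Generator, train_gan
from .losses import LossWeights, csr_loss, ksi_loss
from .openset_eval import EvalReport, evaluate_open_set
from .synthetic_data import LabeledImageSet, make_known_unknown_split

__all__ = [
    "StageConfig",
    "TrainingConfig",
    "ModelBundle",
    "run_known_space_initialization",
    "run_unknown_anchor_generation",
    "run_centralized_space_refinement",
    "run_full_pipeline",
]

VARIANT_MODES = ("csl", "counter_centralized", "random_push", "init_only")


@dataclass
class StageConfig:
    epochs: int
    lr: float

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class TrainingConfig:
    """All pipeline hyperparameters.

    The default constructor is the desk-scale setting used by the test
    suite; :meth:`full_scale` restores the full published schedule
    (50-epoch initialization, 2e4 GAN iterations, 20-epoch refinement,
    ResNet-18 backbone).
    """

    weights: LossWeights = field(default_factory=LossWeights)
    stage1: StageConfig = field(default_factory=lambda: StageConfig(epochs=15, lr=1e-3))
    gan: GanConfig = field(default_factory=GanConfig)
    anchor_quantile: float = 0.70
    delta_max: float = 0.2
    n_anchors: int | None = None  # None = one per training image
    stage3: StageConfig = field(default_factory=lambda: StageConfig(epochs=10, lr=5e-4))
    latent_dim: int = 8
    backbone: str = "small_cnn"
    batch_size: int = 32
    seed: int = 0
    variant_mode: str = "csl"
    threshold_percentile: float = 95.0

    def __post_init__(self):
        if self.variant_mode not in VARIANT_MODES:
            raise ValueError(f"variant_mode must be one of {VARIANT_MODES}")
        if not 0 < self.anchor_quantile <= 1:
            raise ValueError("anchor_quantile must lie in (0, 1]")
        if self.delta_max <= 0:
            raise ValueError("delta_max must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, variant_mode: str = "csl") -> "TrainingConfig":
        """The CPU-friendly test/demo schedule (the class defaults).

        Epoch counts and the GAN iteration budget are scaled down from the
        published schedule; learning rates are scaled up to 1e-3 / 5e-4
        (preserving the published 2:1 stage-1:stage-3 ratio) because the
        small from-scratch backbone must converge within 15 epochs.
        """
        return cls(seed=seed, variant_mode=variant_mode)

    @classmethod
    def full_scale(cls, seed: int = 0, variant_mode: str = "csl") -> "TrainingConfig":
        return cls(
            stage1=StageConfig(epochs=50, lr=1e-4),
            gan=GanConfig(n_iterations=20_000, lr=1e-4, n_layers=9),
            stage3=StageConfig(epochs=20, lr=5e-5),
            backbone="resnet18",
            latent_dim=8,
            seed=seed,
            variant_mode=variant_mode,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelBundle:
    """Everything a trained (or partially trained) run carries."""

    embedder: EmbeddingNetwork
    prototypes: PrototypeSet
    config: TrainingConfig
    generator: Generator | None = None
    discriminator: Discriminator | None = None
    anchors: AnchorSet | None = None
    stages_completed: list[int] = field(default_factory=list)
    logs: dict[str, list] = field(default_factory=dict)
    stage1_state: dict | None = None  # embedder/prototype snapshot after stage 1

    def center(self) -> np.ndarray:
        return self.prototypes.center_numpy()

    def snapshot_stage1(self):
        self.stage1_state = {
            "embedder": self.embedder.net.state_dict(),
            "prototypes": self.prototypes.matrix.copy(),
        }

    def stage1_view(self) -> tuple[EmbeddingNetwork, PrototypeSet]:
        """Reconstruct the post-stage-1 embedder/prototypes (init-only model)."""
        if self.stage1_state is None:
            raise RuntimeError("no stage-1 snapshot recorded")
        emb = build_embedding_network(
            self.embedder.architecture,
            self.embedder.image_size,
            self.embedder.latent_dim,
            seed=0,
            channels=self.embedder.channels,
        )
        emb.net.load_state_dict(self.stage1_state["embedder"])
        protos = PrototypeSet(self.stage1_state["prototypes"].copy(), class_ids=self.prototypes.class_ids)
        return emb, protos


def _iter_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def run_known_space_initialization(train: LabeledImageSet, config: TrainingConfig) -> ModelBundle:
    """Stage 1: train embedder + prototypes on the initialization objective."""
    if len(train) == 0:
        raise ValueError("empty training set")
    known_ids = sorted(np.unique(train.labels).tolist())
    if len(known_ids) < 2:
        raise ValueError("need at least 2 known classes")
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    init_rng = np.random.default_rng(seeds[0])
    batch_rng = np.random.default_rng(seeds[1])

    embedder = build_embedding_network(
        config.backbone, train.images.shape[-1], config.latent_dim, seed=init_rng
    )
    prototypes = PrototypeSet.initialize(len(known_ids), config.latent_dim, seed=init_rng)
    prototypes.class_ids = known_ids

    opt = nn.Adam(embedder.net.parameters() + [prototypes.M], lr=config.stage1.lr)
    log: list[dict] = []
    step = 0
    last_good = None
    for epoch in range(config.stage1.epochs):
        for batch_idx in _iter_minibatches(len(train), config.batch_size, batch_rng):
            z = embedder.embed(train.images[batch_idx], train=True)
            loss = ksi_loss(z, train.labels[batch_idx], prototypes, config.weights)
            if not np.isfinite(loss.item()):
                if last_good is not None:
                    embedder.net.load_state_dict(last_good[0])
                    np.copyto(prototypes.M.data, last_good[1])
                raise FloatingPointError(f"stage-1 loss non-finite at step {step}; restored last checkpoint")
            opt.zero_grad()
            loss.backward()
            opt.step()
            log.append({"step": step, "stage": 1, "loss_name": "ksi", "value": loss.item()})
            step += 1
        last_good = (embedder.net.state_dict(), prototypes.matrix.copy())

    bundle = ModelBundle(embedder=embedder, prototypes=prototypes, config=config)
    bundle.stages_completed.append(1)
    bundle.logs["stage1"] = log
    bundle.snapshot_stage1()
    return bundle


def run_unknown_anchor_generation(bundle: ModelBundle, train: LabeledImageSet) -> ModelBundle:
    """Stage 2: GAN training then anchor rejection sampling (E, M frozen)."""
    if 1 not in bundle.stages_completed:
        raise RuntimeError("stage 1 must complete before anchor generation")
    config = bundle.config
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    gan_cfg = replace(config.gan, seed=int(np.random.default_rng(seeds[2]).integers(2**31)))
    gen, disc, gan_log = train_gan(bundle.embedder, bundle.prototypes, train.images, gan_cfg)

    train_latents = bundle.embedder.embed_numpy(train.images)
    radius = compute_radius_threshold(train_latents, bundle.prototypes, q=config.anchor_quantile)
    anchors = generate_anchor_set(
        bundle.embedder,
        gen,
        bundle.prototypes,
        train.images,
        radius,
        n_target=config.n_anchors,
        delta_max=config.delta_max,
        rng=np.random.default_rng(seeds[3]),
    )
    bundle.generator = gen
    bundle.discriminator = disc
    bundle.anchors = anchors
    bundle.stages_completed.append(2)
    bundle.logs["stage2"] = [
        {"iteration": i, "d_loss": d, "g_adv": a, "g_cycle": c}
        for i, d, a, c in gan_log.as_rows()
    ]
    return bundle


def run_centralized_space_refinement(bundle: ModelBundle, train: LabeledImageSet) -> ModelBundle:
    """Stage 3: fine-tune on known + anchor/proxy batches.

    Each step draws one known batch and one equal-size anchor batch. Proxy
    images are re-embedded by the live embedder every step; the cluster
    penalty sees a detached prototype matrix, so M learns only from the
    known-sample terms.
    """
    config = bundle.config
    mode = config.variant_mode
    if mode == "init_only":
        return bundle
    if bundle.anchors is None:
        raise RuntimeError("refinement in this mode requires an AnchorSet (run stage 2)")
    if 2 not in bundle.stages_completed:
        raise RuntimeError("stage 2 must complete before refinement")
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    batch_rng = np.random.default_rng(seeds[4])

    embedder, prototypes = bundle.embedder, bundle.prototypes
    gen_before = bundle.generator.checksum()
    proxies = bundle.anchors.proxy_images
    opt = nn.Adam(embedder.net.parameters() + [prototypes.M], lr=config.stage3.lr)
    log: list[dict] = []
    step = 0
    for epoch in range(config.stage3.epochs):
        for batch_idx in _iter_minibatches(len(train), config.batch_size, batch_rng):
            z_known = embedder.embed(train.images[batch_idx], train=True)
            a_idx = batch_rng.integers(0, len(proxies), size=len(batch_idx))
            z_anchor = embedder.net(Tensor(proxies[a_idx]))
            if mode == "csl":
                loss = csr_loss(z_known, train.labels[batch_idx], z_anchor, prototypes, config.weights)
            elif mode == "counter_centralized":
                loss = csr_loss(
                    z_known, train.labels[batch_idx], z_anchor, prototypes, config.weights, cluster_sign=-1.0
                )
            elif mode == "random_push":
                loss = csr_loss(z_known, train.labels[batch_idx], None, prototypes, config.weights)
                d2 = squared_distance_matrix(z_anchor, prototypes.M.detach())
                push = -(d2.min(axis=1).maximum(config.weights.epsilon).log()).mean()
                loss = loss + config.weights.theta * push
            else:  # pragma: no cover - guarded by VARIANT_MODES
                raise ValueError(mode)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"stage-3 loss non-finite at step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            log.append({"step": step, "stage": 3, "loss_name": "csr", "value": loss.item()})
            step += 1

    if bundle.generator.checksum() != gen_before:
        raise RuntimeError("stage isolation violated: generator changed during refinement")
    bundle.stages_completed.append(3)
    bundle.logs["stage3"] = log
    return bundle


def anchor_center_distance(bundle: ModelBundle) -> float:
    """Mean ||E(G(f_hat)) - mu||_2 over the anchor proxy images."""
    if bundle.anchors is None:
        raise RuntimeError("no anchors available")
    z = bundle.embedder.embed_numpy(bundle.anchors.proxy_images[:, 0])
    mu = bundle.center()
    return float(np.linalg.norm(z - mu, axis=1).mean())


def run_full_pipeline(
    dataset: LabeledImageSet,
    config: TrainingConfig,
    train_fraction: float = 0.8,
) -> tuple[ModelBundle, EvalReport]:
    """Chain the three stages on a dataset, then evaluate open-set metrics.

    Deterministic given (dataset, config): every random stream is derived
    from ``config.seed``. In ``init_only`` mode stages 2-3 are skipped.
    """
    train, val, unknown = make_known_unknown_split(dataset, train_fraction, seed=config.seed)
    bundle = run_known_space_initialization(train, config)
    if config.variant_mode != "init_only":
        bundle = run_unknown_anchor_generation(bundle, train)
        bundle.logs["anchor_center_distance_before"] = anchor_center_distance(bundle)
        bundle = run_centralized_space_refinement(bundle, train)
        bundle.logs["anchor_center_distance_after"] = anchor_center_distance(bundle)
    report = evaluate_bundle(bundle, train, val, unknown)
    return bundle, report


def evaluate_bundle(
    bundle: ModelBundle,
    train: LabeledImageSet,
    val: LabeledImageSet,
    unknown: LabeledImageSet,
    use_stage1_snapshot: bool = False,
) -> EvalReport:
    """Open-set evaluation of a bundle (optionally of its stage-1 snapshot)."""
    if use_stage1_snapshot:
        embedder, prototypes = bundle.stage1_view()
    else:
        embedder, prototypes = bundle.embedder, bundle.prototypes
    return evaluate_open_set(
        embedder.embed_numpy(train.images),
        embedder.embed_numpy(val.images),
        val.labels,
        embedder.embed_numpy(unknown.images),
        prototypes,
        threshold_percentile=bundle.config.threshold_percentile,
    )


# -- checkpointing -------------------------------------------------------------

def save_bundle(bundle: ModelBundle, out_dir: str | Path):
    """Write checkpoint arrays, sidecar JSON, config and CSV logs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"embedder/{k}": v for k, v in bundle.embedder.net.state_dict().items()}
    arrays["prototypes"] = bundle.prototypes.matrix
    if bundle.generator is not None:
        arrays.update({f"generator/{k}": v for k, v in bundle.generator.state_dict().items()})
    if bundle.discriminator is not None:
        arrays.update({f"discriminator/{k}": v for k, v in bundle.discriminator.state_dict().items()})
    if bundle.anchors is not None:
        arrays["anchors"] = bundle.anchors.anchors
        arrays["anchor_deltas"] = bundle.anchors.deltas
        arrays["anchor_sources"] = bundle.anchors.source_index
        arrays["anchor_proxies"] = bundle.anchors.proxy_images
    np.savez(out / "checkpoint.npz", **arrays)
    save_prototype_sidecar(out / "prototypes.json", bundle.prototypes, bundle.embedder.architecture)
    meta = {
        "stages_completed": bundle.stages_completed,
        "config": bundle.config.to_dict(),
        "latent_dim": bundle.embedder.latent_dim,
        "image_size": bundle.embedder.image_size,
    }
    if bundle.anchors is not None:
        meta["anchors_meta"] = {
            "r": bundle.anchors.radius.r,
            "q": bundle.anchors.radius.q,
            "delta_max": bundle.anchors.delta_max,
            "acceptance_rate": bundle.anchors.acceptance_rate,
            "n_anchors": len(bundle.anchors),
        }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for stage, rows in bundle.logs.items():
        if isinstance(rows, list) and rows:
            import csv as _csv

            with open(out / f"log_{stage}.csv", "w", newline="") as fh:
                writer = _csv.DictWriter(fh, fieldnames=list(rows[0]))
                writer.writeheader()
                writer.writerows(rows)
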