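"""Embedding network, class prototypes and latent-distance computations.

The discriminative embedder ``E`` maps an image to a point in a
d-dimensional latent space. Each known class k owns a learnable prototype
m_k (row k of the K x d matrix M), and the center of the latent layout is
the derived quantity mu = mean_k m_k — recomputed from M on every read so it
can never go stale, with gradients flowing through it into M.

Two backbones are provided: a 4-layer convolutional network sized for small
grayscale images (the default; runs comfortably on one CPU) and a
CIFAR-style ResNet-18 (3x3 stem, eight basic blocks, batch norm) trained
from scratch — no pretrained weights are shipped or downloaded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad

__all__ = [
    "EmbeddingNetwork",
    "PrototypeSet",
    "build_embedding_network",
    "compute_center",
    "squared_distance_matrix",
    "nearest_prototype",
    "save_prototype_sidecar",
    "load_prototype_sidecar",
]


class SmallCNN(nn.Module):
    """conv-relu-pool x3 followed by a linear head to the latent space."""

    def __init__(self, image_size: int, channels: int, latent_dim: int, rng: np.random.Generator, width: int = 16):
        super().__init__()
        if image_size % 8:
            raise ValueError("image_size must be divisible by 8 for three 2x2 pools")
        self.body = nn.Sequential(
            nn.Conv2d(channels, width, 3, rng, pad=1),
            nn.ReLU(),
            nn.AvgPool2d(),
            nn.Conv2d(width, 2 * width, 3, rng, pad=1),
            nn.ReLU(),
            nn.AvgPool2d(),
            nn.Conv2d(2 * width, 4 * width, 3, rng, pad=1),
            nn.ReLU(),
            nn.AvgPool2d(),
            nn.Flatten(),
        )
        feat = 4 * width * (image_size // 8) ** 2
        self.head = nn.Linear(feat, latent_dim, rng)

    def forward(self, x):
        return self.head(self.body(x))


class BasicBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, stride=stride, pad=1, bias=False)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, pad=1, bias=False)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.shortcut = None
        if stride != 1 or c_in != c_out:
            self.shortcut = nn.Conv2d(c_in, c_out, 1, rng, stride=stride, bias=False)
            self.shortcut_bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = x if self.shortcut is None else self.shortcut_bn(self.shortcut(x))
        return (out + skip).relu()


class ResNet18(nn.Module):
    """CIFAR-style ResNet-18 (3x3 stem, no initial max-pool), from scratch."""

    def __init__(self, channels: int, latent_dim: int, rng: np.random.Generator, base_width: int = 16):
        super().__init__()
        w = base_width
        self.stem = nn.Conv2d(channels, w, 3, rng, pad=1, bias=False)
        self.stem_bn = nn.BatchNorm2d(w)
        self.blocks = [
            BasicBlock(w, w, rng),
            BasicBlock(w, w, rng),
            BasicBlock(w, 2 * w, rng, stride=2),
            BasicBlock(2 * w, 2 * w, rng),
            BasicBlock(2 * w, 4 * w, rng, stride=2),
            BasicBlock(4 * w, 4 * w, rng),
            BasicBlock(4 * w, 8 * w, rng, stride=2),
            BasicBlock(8 * w, 8 * w, rng),
        ]
        self.head = nn.Linear(8 * w, latent_dim, rng)

    def forward(self, x):
        out = self.stem_bn(self.stem(x)).relu()
        for block in self.blocks:
            out = block(out)
        out = out.mean(axis=(2, 3))  # global average pool
        return self.head(out)


@dataclass
class EmbeddingNetwork:
    """The embedder E plus the metadata needed to use it safely."""

    net: nn.Module
    architecture: str
    latent_dim: int
    image_size: int
    channels: int = 1

    def embed(self, images: np.ndarray | Tensor, train: bool = False) -> Tensor:
        """Forward a batch of images (n, H, W) or (n, C, H, W) to (n, d).

        In evaluation mode (``train=False``) no tape is recorded and batch
        norm uses running statistics, so the pass is deterministic.
        """
        if isinstance(images, Tensor):
            x = images
            shape = x.shape
        else:
            arr = np.asarray(images, dtype=np.float64)
            if arr.ndim == 3:
                arr = arr[:, None, :, :]
                if self.channels == 3:
                    arr = np.repeat(arr, 3, axis=1)
            shape = arr.shape
            x = Tensor(arr)
        if shape[-1] != self.image_size or shape[-2] != self.image_size or shape[1] != self.channels:
            raise ValueError(
                f"expected (n, {self.channels}, {self.image_size}, {self.image_size}) images, got {shape}"
            )
        if train:
            self.net.train()
            out = self.net(x)
        else:
            self.net.eval()
            with no_grad():
                out = self.net(x)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("embedding produced non-finite latents")
        return out

    def embed_numpy(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode embedding of an arbitrary-size image stack."""
        chunks = []
        for start in range(0, len(images), batch_size):
            chunks.append(self.embed(images[start : start + batch_size]).data)
        return np.concatenate(chunks, axis=0) if chunks else np.empty((0, self.latent_dim))

    def checksum(self) -> str:
        return self.net.checksum()


def build_embedding_network(
    architecture: str,
    image_size: int,
    latent_dim: int,
    seed: int | np.random.Generator = 0,
    channels: int = 1,
) -> EmbeddingNetwork:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if architecture == "small_cnn":
        net = SmallCNN(image_size, channels, latent_dim, rng)
    elif architecture == "resnet18":
        net = ResNet18(channels, latent_dim, rng)
    else:
        raise ValueError(f"unknown architecture {architecture!r}; use 'small_cnn' or 'resnet18'")
    return EmbeddingNetwork(net=net, architecture=architecture, latent_dim=latent_dim, image_size=image_size, channels=channels)


class PrototypeSet:
    """The K x d matrix M of learnable class prototypes.

    ``center()`` returns mu = (1/K) sum_k m_k recomputed from the live M, so
    a read can never observe a stale center; gradients taken through the
    returned tensor reach M.
    """

    def __init__(self, matrix: np.ndarray | Tensor, class_ids: list[int] | None = None):
        if isinstance(matrix, Tensor):
            self.M = matrix
        else:
            self.M = Tensor(np.asarray(matrix, dtype=np.float64), requires_grad=True)
        self.M._is_param = True
        if self.M.ndim != 2 or self.M.shape[0] < 1:
            raise ValueError("prototype matrix must be K x d with K >= 1")
        if not np.all(np.isfinite(self.M.data)):
            raise ValueError("prototype matrix must be finite")
        self.class_ids = list(range(self.M.shape[0])) if class_ids is None else list(class_ids)
        if len(self.class_ids) != self.M.shape[0]:
            raise ValueError("one class id per prototype row required")

    @classmethod
    def initialize(cls, n_classes: int, latent_dim: int, seed: int | np.random.Generator = 0, scale: float = 1.0):
        """Rows drawn from N(0, scale^2 I_d) with a fixed seed."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(scale * rng.standard_normal((n_classes, latent_dim)))

    @property
    def n_classes(self) -> int:
        return self.M.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.M.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        return self.M.data

    def center(self) -> Tensor:
        return compute_center(self)

    def center_numpy(self) -> np.ndarray:
        return self.M.data.mean(axis=0)

    def checksum(self) -> str:
        import hashlib

        return hashlib.sha256(self.M.data.tobytes()).hexdigest()


def compute_center(prototypes: PrototypeSet) -> Tensor:
    """mu = arithmetic mean of the prototype rows (differentiable)."""
    if prototypes.n_classes < 1:
        raise ValueError("cannot compute the center of an empty prototype set")
    return prototypes.M.mean(axis=0)


def squared_distance_matrix(latents, points) -> Tensor:
    """Pairwise squared Euclidean distances, (n, d) x (P, d) -> (n, P).

    Accepts tensors or arrays; gradients flow to tensor inputs. Uses the
    expansion ||z||^2 + ||p||^2 - 2 z.p with a clamp at zero to absorb
    round-off.
    """
    z = Tensor.as_tensor(latents)
    p = Tensor.as_tensor(points)
    if z.ndim == 1:
        z = z.reshape(1, z.shape[0])
    if p.ndim == 1:
        p = p.reshape(1, p.shape[0])
    if z.shape[1] != p.shape[1]:
        raise ValueError(f"latent dim {z.shape[1]} != point dim {p.shape[1]}")
    zz = (z**2.0).sum(axis=1, keepdims=True)
    pp = (p**2.0).sum(axis=1, keepdims=True).T
    cross = z @ p.T
    return (zz + pp - 2.0 * cross).maximum(0.0)


def nearest_prototype(latents: np.ndarray, prototypes: PrototypeSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample nearest class id and squared distance to it.

    Ties are broken toward the smallest class id (argmin convention).
    """
    with no_grad():
        d2 = squared_distance_matrix(np.atleast_2d(np.asarray(latents, dtype=np.float64)), prototypes.M.data).data
    idx = np.argmin(d2, axis=1)
    ids = np.asarray(prototypes.class_ids)[idx]
    return ids, d2[np.arange(len(idx)), idx]


# -- serialization ------------------------------------------------------------

def save_prototype_sidecar(path: str | Path, prototypes: PrototypeSet, architecture: str, class_names: dict[int, str] | None = None):
    """Write the human-readable prototype sidecar (`prototypes.json`)."""
    payload = {
        "prototypes": prototypes.matrix.tolist(),
        "center": prototypes.center_numpy().tolist(),
        "class_ids": prototypes.class_ids,
        "latent_dim": prototypes.latent_dim,
        "architecture": architecture,
        "class_names": {str(k): v for k, v in (class_names or {}).items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_prototype_sidecar(path: str | Path) -> tuple[PrototypeSet, dict]:
    payload = json.loads(Path(path).read_text())
    protos = PrototypeSet(np.array(payload["prototypes"]), class_ids=payload["class_ids"])
    return protos, payload
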