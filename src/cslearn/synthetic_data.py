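"""Parametric synthetic image datasets with disjoint known/unknown classes.

Each class is an anisotropic 2-D Gaussian intensity blob parameterized by
its center, orientation and aspect ratio; samples within a class share those
parameters up to a small jitter, plus additive pixel noise. Known-class
centers live in the left half of the image and unknown-class centers in the
right half, so "unknown" is well defined by construction: no unknown class
can coincide with a known one in parameter space.

This is a deliberately learnable stand-in for real radiograph/dermoscopy
collections: blob classes are separable by any reasonable image classifier,
and difficulty is controlled by ``noise_sigma``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticConfig",
    "LabeledImageSet",
    "ClassParams",
    "render_sample",
    "generate_dataset",
    "make_known_unknown_split",
    "save_image_folder",
    "load_image_folder",
]


@dataclass(frozen=True)
class SyntheticConfig:
    image_size: int = 32
    n_known_classes: int = 4
    n_unknown_classes: int = 2
    samples_per_class: int = 50
    noise_sigma: float = 0.02
    seed: int = 0
    # per-sample jitter of class parameters (pixels / radians); gives each
    # class genuine intra-class variance beyond pixel noise
    center_jitter: float = 1.0
    angle_jitter: float = 0.1

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "SyntheticConfig":
        """The end-to-end demonstration condition.

        K=4 known / U=2 unknown at 32x32; 62 samples per class so an 80%
        known-class split yields 200 training images. Noise sigma 0.2 puts
        the task in a non-saturated regime: classes stay learnable, but
        unknown detection is no longer solved by any freshly initialized
        space, leaving measurable headroom for the refinement stage.
        """
        return cls(samples_per_class=62, noise_sigma=0.2, seed=seed)

    def __post_init__(self):
        if self.n_known_classes < 2:
            raise ValueError("need at least 2 known classes")
        if self.n_unknown_classes < 0:
            raise ValueError("n_unknown_classes must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")


@dataclass(frozen=True)
class ClassParams:
    """Blob parameters defining one class."""

    center: tuple[float, float]  # (row, col) in pixels
    angle: float  # orientation, radians
    aspect: float  # ratio of major to minor axis, > 0


@dataclass
class LabeledImageSet:
    """Images with integer class labels and a known/unknown mask."""

    images: np.ndarray  # (n, H, W), values in [0, 1]
    labels: np.ndarray  # (n,) integer class ids
    known_mask: np.ndarray  # (n,) True where the sample's class is known
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.images)
        if len(self.labels) != n or len(self.known_mask) != n:
            raise ValueError("images, labels and known_mask must align")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")
        known = set(np.unique(self.labels[self.known_mask]).tolist())
        unknown = set(np.unique(self.labels[~self.known_mask]).tolist())
        if known & unknown:
            raise ValueError("known and unknown class id sets must be disjoint")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def known_class_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.known_mask])

    @property
    def unknown_class_ids(self) -> np.ndarray:
        return np.unique(self.labels[~self.known_mask])

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            images=self.images[idx],
            labels=self.labels[idx],
            known_mask=self.known_mask[idx],
            class_names=dict(self.class_names),
        )


def render_sample(
    class_params: ClassParams,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one anisotropic Gaussian blob image with additive noise.

    Deterministic given ``rng`` state; with ``noise_sigma=0`` (or no rng) the
    output is the pure blob, whose peak sits at the nearest pixel to the
    blob center.
    """
    s = config.image_size
    r0, c0 = class_params.center
    if not (0 <= r0 < s and 0 <= c0 < s):
        raise ValueError(f"blob center {class_params.center} outside image bounds")
    if class_params.aspect <= 0:
        raise ValueError("aspect ratio must be positive")
    sigma = s / 8.0
    s_major = sigma * np.sqrt(class_params.aspect)
    s_minor = sigma / np.sqrt(class_params.aspect)
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    dr, dc = rows - r0, cols - c0
    ca, sa = np.cos(class_params.angle), np.sin(class_params.angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    img = np.exp(-0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2))
    if config.noise_sigma > 0 and rng is not None:
        img = img + config.noise_sigma * rng.standard_normal((s, s))
    return np.clip(img, 0.0, 1.0)


def _draw_class_params(config: SyntheticConfig, rng: np.random.Generator) -> list[ClassParams]:
    """Known-class centers in the left half-plane, unknown in the right."""
    s = config.image_size
    margin = s / 8.0
    params: list[ClassParams] = []
    for class_id in range(config.n_known_classes + config.n_unknown_classes):
        known = class_id < config.n_known_classes
        lo, hi = (margin, s / 2.0 - 1.0) if known else (s / 2.0 + 1.0, s - margin)
        col = rng.uniform(lo, hi)
        row = rng.uniform(margin, s - margin)
        params.append(
            ClassParams(
                center=(row, col),
                angle=rng.uniform(0, np.pi),
                aspect=rng.uniform(1.5, 3.0),
            )
        )
    return params


def generate_dataset(config: SyntheticConfig) -> LabeledImageSet:
    """Generate the full K+U class dataset; pure function of (config, seed)."""
    rng = np.random.default_rng(config.seed)
    class_params = _draw_class_params(config, rng)
    s = config.image_size
    images, labels, known = [], [], []
    for class_id, base in enumerate(class_params):
        is_known = class_id < config.n_known_classes
        for _ in range(config.samples_per_class):
            jr, jc = config.center_jitter * rng.standard_normal(2)
            center = (
                float(np.clip(base.center[0] + jr, 0, s - 1)),
                float(np.clip(base.center[1] + jc, 0, s - 1)),
            )
            jittered = ClassParams(
                center=center,
                angle=base.angle + config.angle_jitter * rng.standard_normal(),
                aspect=base.aspect,
            )
            images.append(render_sample(jittered, config, rng))
            labels.append(class_id)
            known.append(is_known)
    names = {
        i: (f"known_{i}" if i < config.n_known_classes else f"unknown_{i}")
        for i in range(len(class_params))
    }
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.array(labels, dtype=np.int64),
        known_mask=np.array(known, dtype=bool),
        class_names=names,
    )


def make_split_indices(
    dataset: LabeledImageSet, train_fraction: float = 0.8, seed: int = 0
) -> dict[str, np.ndarray]:
    """Index arrays for the train/val/unknown partition (see below)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for class_id in dataset.known_class_ids:
        idx = np.flatnonzero(dataset.labels == class_id)
        if len(idx) < 2:
            raise ValueError(f"known class {class_id} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return {
        "train": np.sort(np.concatenate(train_idx)),
        "val": np.sort(np.concatenate(val_idx)),
        "unknown": np.flatnonzero(~dataset.known_mask),
    }


def make_known_unknown_split(
    dataset: LabeledImageSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Split into (train known, validation known, unknown) subsets.

    Unknown-class samples all go to the unknown evaluation set. Known
    classes are split per class at ``train_fraction`` (rounded, with at
    least one sample on each side). Shuffling within a class is seeded; no
    sample appears in more than one subset.
    """
    idx = make_split_indices(dataset, train_fraction, seed)
    return dataset.subset(idx["train"]), dataset.subset(idx["val"]), dataset.subset(idx["unknown"])


# -- image-folder round trip ---------------------------------------------------

def save_image_folder(
    dataset: LabeledImageSet, out_dir: str | Path, split_indices: dict[str, np.ndarray] | None = None
):
    """Write PNGs as `<class_name>/<idx>.png` plus manifest.csv / split.csv."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
        name = dataset.class_names.get(int(label), f"class_{label}")
        cls_dir = out / name
        cls_dir.mkdir(exist_ok=True)
        rel = f"{name}/{i:05d}.png"
        Image.fromarray(np.round(img * 255).astype(np.uint8), mode="L").save(out / rel)
        rows.append((rel, int(label), name, bool(dataset.known_mask[i])))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class_id", "class_name", "known"])
        writer.writerows(rows)
    if split_indices is not None:
        with open(out / "split.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "subset"])
            for subset_name, idx in split_indices.items():
                for i in idx:
                    writer.writerow([rows[int(i)][0], subset_name])


def load_image_folder(folder: str | Path) -> LabeledImageSet:
    """Read a `<class_name>/<idx>.png` + manifest.csv layout back."""
    from PIL import Image

    folder = Path(folder)
    manifest = folder / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest.csv in {folder}")
    images, labels, known, names = [], [], [], {}
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(folder / row["path"]).convert("L"), dtype=np.float64) / 255.0
            images.append(arr)
            labels.append(int(row["class_id"]))
            known.append(row["known"] in ("True", "true", "1"))
            names[int(row["class_id"])] = row["class_name"]
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.array(labels, dtype=np.int64),
        known_mask=np.array(known, dtype=bool),
        class_names=names,
    )
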