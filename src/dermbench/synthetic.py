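"""Synthetic class-conditional embeddings emulating CNN feature extractors.

The real study extracted deep features from dermoscopic images of four
lesion classes (basal cell carcinoma, melanoma, pigmented benign keratosis,
vascular lesions) with four backbone networks whose penultimate layers emit
4096 / 2048 / 1280 / 2048 features.  This module generates tables with the
same statistical shape: independent Gaussian features in which a known
subset of "informative" columns carries class-specific mean offsets placed
on a (rotated) regular simplex, so that the pairwise distance between class
mean vectors equals ``effect_size`` within-class standard deviations.  Every
downstream stage — wrapper selection, classification, ranking — is testable
against the planted ground truth without any image download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import LabeledFeatureTable

__all__ = [
    "ConfigurationError",
    "EmbeddingProfile",
    "SplitSpec",
    "default_profiles",
    "generate_embeddings",
    "stratified_split",
]

#: Lesion classes of the 4-class study subset.
DEFAULT_CLASSES = (
    "basal_cell_carcinoma",
    "melanoma",
    "pigmented_benign_keratosis",
    "vascular_lesions",
)

#: Default imbalanced class sizes summing to 1466 (a config default, not a
#: claim about the original image subset, whose per-class counts were never
#: published).
DEFAULT_CLASS_SIZES = (478, 438, 376, 174)


class ConfigurationError(ValueError):
    """An embedding profile or split specification is invalid."""


@dataclass
class EmbeddingProfile:
    """Statistical recipe for one extractor's synthetic feature table."""

    name: str = "alexnet-like"
    dimension: int = 4096
    n_informative: int = 64
    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.dimension < 1 or self.n_informative < 1:
            raise ConfigurationError("dimension and n_informative must be >= 1")
        if self.n_informative > self.dimension:
            raise ConfigurationError("n_informative cannot exceed dimension")
        if len(self.class_sizes) != len(self.class_names):
            raise ConfigurationError("class_sizes and class_names length mismatch")
        if any(int(s) < 1 for s in self.class_sizes):
            raise ConfigurationError("all class sizes must be >= 1")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass
class SplitSpec:
    """Stratified train/validation/test proportions (default 70/15/15)."""

    train_fraction: float = 0.70
    validation_fraction: float = 0.15
    test_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f <= 0 for f in fracs):
            raise ConfigurationError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


def default_profiles(
    total: int = 1466, n_informative: int = 64, effect_size: float = 3.0, seed: int = 0
) -> list[EmbeddingProfile]:
    """The four extractor profiles of the study grid.

    Dimensions follow the penultimate-layer widths of the four backbones
    (AlexNet 4096, InceptionV3 2048, MobileNetV2 1280, ResNet-50 2048).
    """
    sizes = _scaled_class_sizes(total)
    dims = {
        "alexnet-like": 4096,
        "inception-like": 2048,
        "mobilenet-like": 1280,
        "resnet-like": 2048,
    }
    return [
        EmbeddingProfile(
            name=name,
            dimension=dim,
            n_informative=n_informative,
            class_sizes=sizes,
            effect_size=effect_size,
            seed=seed + offset,
        )
        for offset, (name, dim) in enumerate(dims.items())
    ]


def _scaled_class_sizes(total: int) -> tuple[int, ...]:
    """Scale the default imbalance to a requested total (largest remainder)."""
    base = np.asarray(DEFAULT_CLASS_SIZES, dtype=float)
    exact = base / base.sum() * total
    sizes = np.floor(exact).astype(int)
    sizes = np.maximum(sizes, 1)
    short = total - sizes.sum()
    order = np.argsort(-(exact - np.floor(exact)))
    for i in range(abs(int(short))):
        sizes[order[i % len(sizes)]] += 1 if short > 0 else -1
    return tuple(int(s) for s in sizes)


def _class_mean_offsets(n_classes: int, n_informative: int, rng: np.random.Generator) -> np.ndarray:
    """Class mean directions: a regular simplex with unit pairwise distance,
    rotated into the informative subspace so every informative column carries
    signal generically.

    Returns an (n_classes, n_informative) array whose rows are pairwise
    equidistant at distance 1 (shrunk distance if n_informative < n_classes-1,
    where a full simplex cannot be embedded; the result is then rescaled so
    the *mean* pairwise distance is 1).
    """
    k = n_classes
    # Regular simplex in k-1 dims with unit pairwise distance.
    verts = np.eye(k) - 1.0 / k
    # Orthonormal basis of the (k-1)-dim affine hull.
    u, s, _ = np.linalg.svd(verts, full_matrices=False)
    coords = u[:, : k - 1] * s[: k - 1]  # (k, k-1), pairwise distance sqrt(2)
    coords /= np.sqrt(2.0)
    d = min(n_informative, k - 1)
    coords = coords[:, :d]
    if n_informative >= k - 1:
        # Rotate into n_informative dims with a random orthonormal frame.
        g = rng.standard_normal((n_informative, k - 1))
        q, _ = np.linalg.qr(g)
        offsets = coords @ q.T
    else:
        offsets = coords
    # Rescale so the mean pairwise distance equals 1 (exact projection can
    # shrink distances when the simplex does not fit).
    dists = [
        np.linalg.norm(offsets[i] - offsets[j])
        for i in range(k)
        for j in range(i + 1, k)
    ]
    mean_d = float(np.mean(dists))
    if mean_d > 0:
        offsets = offsets / mean_d
    return offsets


def generate_embeddings(profile: EmbeddingProfile) -> LabeledFeatureTable:
    """Generate a labeled feature table from a class-conditional Gaussian model.

    Informative columns receive per-class mean offsets on a fixed (seeded)
    simplex scaled by ``effect_size * noise_sd``; the remaining columns are
    class-independent noise.  Identical profile and seed yield a bit-identical
    table.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    n_classes = len(profile.class_sizes)
    n_total = int(sum(profile.class_sizes))

    offsets = _class_mean_offsets(n_classes, profile.n_informative, rng)
    offsets = offsets * (profile.effect_size * profile.noise_sd)

    values = rng.normal(0.0, profile.noise_sd, size=(n_total, profile.dimension))
    labels = np.empty(n_total, dtype=object)
    row = 0
    for cls, size, offset in zip(profile.class_names, profile.class_sizes, offsets):
        values[row : row + size, : profile.n_informative] += offset
        labels[row : row + size] = cls
        row += size

    informative = np.zeros(profile.dimension, dtype=bool)
    informative[: profile.n_informative] = True
    width = max(4, len(str(profile.dimension)))
    feature_ids = [f"feature_{i + 1:0{width}d}" for i in range(profile.dimension)]
    return LabeledFeatureTable(
        values=values,
        labels=labels.astype(str),
        feature_ids=feature_ids,
        informative_mask=informative,
    )


def stratified_split(
    table: LabeledFeatureTable, spec: SplitSpec | None = None
) -> tuple[LabeledFeatureTable, LabeledFeatureTable, LabeledFeatureTable]:
    """Partition rows into train/validation/test, stratified by class.

    Each class is shuffled and allocated to the three partitions by
    largest-remainder rounding, so per-class proportions match the spec
    within one sample and the union of partitions is exactly the input.

    Raises
    ------
    ConfigurationError
        If the spec is invalid or any class has fewer samples than the
        number of partitions.
    """
    spec = spec or SplitSpec()
    spec.validate()
    fracs = np.array(
        [spec.train_fraction, spec.validation_fraction, spec.test_fraction]
    )
    rng = np.random.default_rng(spec.seed)
    parts: list[list[int]] = [[], [], []]
    for cls in table.class_ids:
        idx = np.flatnonzero(table.labels == cls)
        if idx.size < 3:
            raise ConfigurationError(
                f"class {cls!r} has {idx.size} samples; need at least 3 to split"
            )
        rng.shuffle(idx)
        exact = fracs * idx.size
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        # Give leftover samples to partitions with the largest remainders;
        # ties go to the earlier partition (stable argsort on -remainder).
        for j in np.argsort(-remainder, kind="stable")[: idx.size - counts.sum()]:
            counts[j] += 1
        bounds = np.cumsum(counts)
        parts[0].extend(idx[: bounds[0]])
        parts[1].extend(idx[bounds[0] : bounds[1]])
        parts[2].extend(idx[bounds[1] :])
    return tuple(
        table.subset_rows(np.sort(np.asarray(p, dtype=int))) for p in parts
    )
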