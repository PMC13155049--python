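"""Seeded two-class synthetic histology-like images with ground-truth masks.

The generator emulates the visual contrast that drives benign/malignant
discrimination in H&E patches: the malignant class contains 1-3 clusters of
densely packed, overlapping, irregular, high-contrast blobs (a stand-in for
dense malignant nuclei), and the cluster footprint after morphological
closing is recorded as an exact binary ground-truth mask.  The benign class
contains only a handful of sparse, round, low-contrast blobs and carries an
all-zero mask.  On top of image generation the module provides the standard
dataset plumbing: patient-wise stratified splitting, online augmentation
(rotations, flips, color jitter) that co-transforms the mask, per-channel
standardization, and an on-disk PNG/CSV layout.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.morphology import closing as _closing, disk

BENIGN, MALIGNANT = 0, 1
CLASS_NAMES = {BENIGN: "benign", MALIGNANT: "malignant"}


@dataclass
class GeneratorParams:
    """Morphology and contrast knobs for the synthetic patch generator.

    ``contrast`` is the guaranteed intensity separation between the planted
    malignant region and the surrounding tissue: malignant blobs are
    darkened by 1.6-2.0x this value, so the mean intensity inside the mask
    sits more than ``contrast`` below the outside mean.
    """

    height: int = 64
    width: int = 64
    # benign morphology: sparse, round, faint
    benign_blob_count: tuple[int, int] = (5, 15)
    benign_radius: tuple[float, float] = (2.0, 4.0)
    benign_contrast: float = 0.08
    benign_irregularity: float = 0.08
    # malignant morphology: dense irregular clusters
    cluster_count: tuple[int, int] = (1, 3)
    blobs_per_cluster: tuple[int, int] = (20, 60)
    malignant_radius: tuple[float, float] = (1.5, 3.5)
    contrast: float = 0.35
    malignant_irregularity: float = 0.4
    closing_radius: int = 2
    # background texture
    base_color: tuple[float, float, float] = (0.88, 0.76, 0.84)
    noise: float = 0.02

    def validate(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("image size must be at least 32x32")
        for name in ("benign_blob_count", "benign_radius", "cluster_count",
                     "blobs_per_cluster", "malignant_radius"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"empty or invalid range for {name}: ({lo}, {hi})")


@dataclass
class LabeledImage:
    pixels: np.ndarray          # (H, W, 3) floats in [0, 1]
    label: int                  # 0 benign, 1 malignant
    gt_mask: np.ndarray         # (H, W) bool; all-False for benign
    patient_id: str = "p0"


@dataclass
class DatasetSplit:
    train: list[LabeledImage]
    val: list[LabeledImage]
    test: list[LabeledImage]

    def partitions(self):
        return {"train": self.train, "val": self.val, "test": self.test}


def _blob_mask(shape, cy, cx, radius, irregularity, rng, n_vertices=16):
    """Boolean mask of one irregular blob (radius perturbed per vertex)."""
    angles = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    radii = radius * (1.0 + irregularity * rng.uniform(-1, 1, size=n_vertices))
    radii = np.clip(radii, 0.5, None)
    rr, cc = draw_polygon(cy + radii * np.sin(angles), cx + radii * np.cos(angles), shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def generate_image(label: int, params: GeneratorParams | None = None,
                   seed: int = 0) -> LabeledImage:
    """Generate one synthetic patch; deterministic for fixed (label, params, seed)."""
    params = params or GeneratorParams()
    params.validate()
    if label not in (BENIGN, MALIGNANT):
        raise ValueError(f"label must be {BENIGN} (benign) or {MALIGNANT} (malignant)")
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    shape = (h, w)

    # textured pink background: smooth low-frequency tint + pixel noise
    img = np.empty((h, w, 3))
    yy, xx = np.mgrid[0:h, 0:w]
    tint = 0.03 * np.sin(2 * np.pi * (yy * rng.uniform(0.5, 2) / h
                                      + xx * rng.uniform(0.5, 2) / w)
                         + rng.uniform(0, 2 * np.pi))
    for ch, base in enumerate(params.base_color):
        img[:, :, ch] = base + tint
    img += rng.normal(0.0, params.noise, size=img.shape)

    # sparse faint round blobs appear in both classes (benign tissue texture)
    n_benign = rng.integers(params.benign_blob_count[0], params.benign_blob_count[1] + 1)
    for _ in range(n_benign):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(*params.benign_radius)
        m = _blob_mask(shape, cy, cx, r, params.benign_irregularity, rng)
        depth = params.benign_contrast * rng.uniform(0.6, 1.0)
        img[m] -= depth * np.array([0.6, 1.0, 0.5])

    gt_mask = np.zeros(shape, dtype=bool)
    if label == MALIGNANT:
        blob_union = np.zeros(shape, dtype=bool)
        n_clusters = rng.integers(params.cluster_count[0], params.cluster_count[1] + 1)
        margin = max(h, w) / 6
        for _ in range(n_clusters):
            ccy = rng.uniform(margin, h - margin)
            ccx = rng.uniform(margin, w - margin)
            spread = rng.uniform(0.06, 0.10) * max(h, w)
            n_blobs = rng.integers(params.blobs_per_cluster[0], params.blobs_per_cluster[1] + 1)
            for _ in range(n_blobs):
                cy = ccy + rng.normal(0, spread)
                cx = ccx + rng.normal(0, spread)
                r = rng.uniform(*params.malignant_radius)
                m = _blob_mask(shape, cy, cx, r, params.malignant_irregularity, rng)
                depth = params.contrast * rng.uniform(1.6, 2.0)
                img[m] -= depth * np.array([0.7, 1.0, 0.6])
                blob_union |= m
        gt_mask = _closing(blob_union, disk(params.closing_radius)).astype(bool)
        # darken any closing-filled gaps so the mask interior is uniformly
        # high-contrast (densely packed nuclei leave no pale holes)
        gap = gt_mask & ~blob_union
        img[gap] -= params.contrast * 1.6 * np.array([0.7, 1.0, 0.6])

    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(pixels=img, label=int(label), gt_mask=gt_mask)


# --- dataset assembly -----------------------------------------------------

def generate_dataset(n_per_class: int, fractions=(0.8, 0.1, 0.1),
                     images_per_patient: int = 1, seed: int = 0,
                     params: GeneratorParams | None = None) -> DatasetSplit:
    """Patient-wise stratified train/val/test split of generated images.

    Each synthetic patient contributes ``images_per_patient`` images of a
    single class; every patient's images land in exactly one partition.
    With unit patient groups and exactly divisible counts the partition
    sizes match the requested fractions exactly.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ValueError("fractions must be three nonnegative values summing to 1")
    if n_per_class < 1 or images_per_patient < 1:
        raise ValueError("n_per_class and images_per_patient must be positive")
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    parts: dict[str, list[LabeledImage]] = {"train": [], "val": [], "test": []}
    for label in (BENIGN, MALIGNANT):
        n_patients = -(-n_per_class // images_per_patient)  # ceil
        order = rng.permutation(n_patients)
        # patient-level partition counts: floored, remainder to the largest
        # fractional parts (stable, so exact when divisible)
        ideal = np.array(fractions) * n_patients
        counts = np.floor(ideal).astype(int)
        for k in np.argsort(-(ideal - counts)):
            if counts.sum() == n_patients:
                break
            counts[k] += 1
        bounds = np.cumsum(counts)
        assignment = {}
        for rank, pat in enumerate(order):
            part = "train" if rank < bounds[0] else ("val" if rank < bounds[1] else "test")
            assignment[pat] = part
        for i in range(n_per_class):
            pat = i // images_per_patient
            img_seed = int((seed * 2_654_435_761 + label * 97_561_103 + i * 1_299_709) % (2**31 - 1))
            img = generate_image(label, params, seed=img_seed)
            img.patient_id = f"{CLASS_NAMES[label][0]}{pat:05d}"
            parts[assignment[pat]].append(img)
    for part in parts.values():
        rng.shuffle(part)
    return DatasetSplit(**parts)


# --- augmentation ---------------------------------------------------------

@dataclass
class AugmentConfig:
    """On-the-fly augmentation: 90-degree rotations, flips, color jitter."""

    rotate: bool = True          # one of -90/0/+90 degrees
    hflip: bool = True
    vflip: bool = True
    brightness_jitter: float = 0.10
    contrast_jitter: float = 0.10
    color_jitter: float = 0.05   # independent per-channel offset

    @classmethod
    def identity(cls):
        return cls(rotate=False, hflip=False, vflip=False,
                   brightness_jitter=0.0, contrast_jitter=0.0, color_jitter=0.0)


def augment(image: LabeledImage, seed: int,
            config: AugmentConfig | None = None) -> LabeledImage:
    """Random label-preserving transform; the mask is co-transformed.

    Deterministic per seed; the identity config returns the input unchanged.
    """
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    px, mask = image.pixels, image.gt_mask
    if config.rotate:
        k = int(rng.integers(0, 3)) - 1  # -1, 0, +1 quarter turns
        if k:
            px = np.rot90(px, k, axes=(0, 1))
            mask = np.rot90(mask, k, axes=(0, 1))
    if config.hflip and rng.random() < 0.5:
        px, mask = px[:, ::-1], mask[:, ::-1]
    if config.vflip and rng.random() < 0.5:
        px, mask = px[::-1], mask[::-1]
    if config.brightness_jitter or config.contrast_jitter or config.color_jitter:
        px = px.astype(float)
        if config.contrast_jitter:
            scale = 1.0 + rng.uniform(-config.contrast_jitter, config.contrast_jitter)
            px = (px - px.mean()) * scale + px.mean()
        if config.brightness_jitter:
            px = px + rng.uniform(-config.brightness_jitter, config.brightness_jitter)
        if config.color_jitter:
            px = px + rng.uniform(-config.color_jitter, config.color_jitter, size=3)
        px = np.clip(px, 0.0, 1.0)
    return LabeledImage(pixels=np.ascontiguousarray(px), label=image.label,
                        gt_mask=np.ascontiguousarray(mask), patient_id=image.patient_id)


# --- normalization --------------------------------------------------------

@dataclass
class ChannelStats:
    mean: np.ndarray  # (3,)
    std: np.ndarray   # (3,)


def channel_stats(pixels: np.ndarray) -> ChannelStats:
    """Per-channel mean/std over a stack of images (N, H, W, 3)."""
    pixels = np.asarray(pixels, dtype=float)
    mean = pixels.mean(axis=(0, 1, 2))
    std = pixels.std(axis=(0, 1, 2))
    for ch, s in enumerate(std):
        if s < 1e-12:
            raise ValueError(f"channel {ch} has zero variance; cannot standardize")
    return ChannelStats(mean=mean, std=std)


def normalize(pixels: np.ndarray, stats: ChannelStats | None = None):
    """Standardize a stack of images to zero mean / unit variance per channel.

    When ``stats`` is omitted they are computed from the stack itself (use
    training-partition stats for val/test to avoid leakage).  Returns
    ``(standardized_stack, stats)``.
    """
    pixels = np.asarray(pixels, dtype=float)
    if stats is None:
        stats = channel_stats(pixels)
    return (pixels - stats.mean) / stats.std, stats


def stack_pixels(images: list[LabeledImage]) -> np.ndarray:
    return np.stack([im.pixels for im in images])


def labels_of(images: list[LabeledImage]) -> np.ndarray:
    return np.array([im.label for im in images], dtype=int)


# --- simple separability features (used to sanity-check the generator) ----

def intensity_features(image: LabeledImage, dark_threshold: float | None = None) -> np.ndarray:
    """(mean intensity, dark-pixel fraction) — a 2-feature summary on which
    the two classes are linearly separable at default contrast."""
    params = GeneratorParams()
    if dark_threshold is None:
        dark_threshold = float(np.mean(params.base_color)) - params.contrast
    gray = image.pixels.mean(axis=2)
    return np.array([gray.mean(), float((gray < dark_threshold).mean())])


# --- on-disk layout -------------------------------------------------------

def save_dataset(split: DatasetSplit, root: str, force: bool = False) -> str:
    """Write root/{train,val,test}/{benign,malignant}/img_XXXX.png (+ masks)
    and a manifest.csv; returns the manifest path."""
    if os.path.isdir(root) and os.listdir(root) and not force:
        raise FileExistsError(f"{root} exists and is not empty (use force)")
    rows = []
    for part, images in split.partitions().items():
        for idx, im in enumerate(images):
            d = os.path.join(root, part, CLASS_NAMES[im.label])
            os.makedirs(d, exist_ok=True)
            path = os.path.join(d, f"img_{idx:04d}.png")
            iio.imwrite(path, (im.pixels * 255).round().astype(np.uint8))
            if im.label == MALIGNANT:
                iio.imwrite(os.path.join(d, f"img_{idx:04d}_mask.png"),
                            (im.gt_mask * 255).astype(np.uint8))
            rows.append({"image_path": os.path.relpath(path, root),
                         "label": im.label, "patient_id": im.patient_id, "split": part})
    manifest = os.path.join(root, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(root: str) -> DatasetSplit:
    manifest = pd.read_csv(os.path.join(root, "manifest.csv"))
    parts: dict[str, list[LabeledImage]] = {"train": [], "val": [], "test": []}
    for row in manifest.itertuples():
        path = os.path.join(root, row.image_path)
        px = iio.imread(path).astype(float) / 255.0
        mask_path = path.replace(".png", "_mask.png")
        if row.label == MALIGNANT and os.path.exists(mask_path):
            mask = iio.imread(mask_path) > 127
        else:
            mask = np.zeros(px.shape[:2], dtype=bool)
        parts[row.split].append(LabeledImage(pixels=px, label=int(row.label),
                                             gt_mask=mask, patient_id=str(row.patient_id)))
    return DatasetSplit(**parts)
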