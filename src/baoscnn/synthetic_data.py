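"""Synthetic habitat-morphotype image generator, patch-grid slicing and
classified-patch colour overlays.

Four parametric texture families stand in for the four visual classes of
patch-based benthic habitat imagery:

* ``strap`` — oriented sinusoidal gratings (long strap-like leaves),
* ``oval`` — bright elliptical blobs on a dark ground (rounded leaves),
* ``branched`` — recursive branching line segments (ferny/branched stems),
* ``background`` — low-frequency noise with speckle (sand, debris, water).

Whole images carry the class label; a 6 x 6 patch grid slices each image
into 36 patches that inherit the parent label, mirroring the patch-based
labelling protocol of field datasets.  The generator is deliberately
minimal: it produces separable textures, not photorealistic seagrass.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from baoscnn.cnn_fitness import Dataset

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_PALETTE",
    "SyntheticSpec",
    "PatchSet",
    "Overlay",
    "generate_dataset",
    "slice_grid",
    "slice_dataset",
    "overlay",
    "write_dataset",
    "load_dataset",
]

CLASS_NAMES = ("strap", "oval", "branched", "background")

# blue / yellow / purple / maroon, RGB in [0, 1]
DEFAULT_PALETTE = (
    (0.12, 0.30, 0.85),
    (0.95, 0.85, 0.15),
    (0.55, 0.20, 0.65),
    (0.55, 0.10, 0.12),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the generator.

    ``image_size`` must be divisible by the grid so patches tile exactly.
    ``noise_sd`` is additive Gaussian pixel noise on the unit intensity
    scale.
    """

    per_class: int = 50
    image_size: tuple[int, int] = (24, 24)
    rows: int = 6
    cols: int = 6
    noise_sd: float = 0.05
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h % self.rows or w % self.cols:
            raise ValueError("image size must be divisible by the patch grid")
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def _grating(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Oriented sinusoidal grating: parallel strap-like bands."""
    theta = rng.uniform(-0.7, 0.7)  # radians off vertical
    cycles = rng.uniform(3.0, 6.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    y, x = np.mgrid[0:h, 0:w]
    u = (x * np.cos(theta) + y * np.sin(theta)) / w
    img = 0.5 + 0.5 * np.sin(2.0 * np.pi * cycles * u + phase)
    return 0.15 + 0.7 * img


def _ovals(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Bright elliptical blobs on a dark ground."""
    img = np.full((h, w), 0.12)
    y, x = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(4, 8)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(0.10, 0.22) * w
        b = a * rng.uniform(0.5, 0.8)
        phi = rng.uniform(0.0, np.pi)
        xr = (x - cx) * np.cos(phi) + (y - cy) * np.sin(phi)
        yr = -(x - cx) * np.sin(phi) + (y - cy) * np.cos(phi)
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        img[mask] = rng.uniform(0.75, 0.95)
    return img


def _draw_segment(img: np.ndarray, p0, p1, value: float) -> None:
    n = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1])) * 2) + 2
    t = np.linspace(0.0, 1.0, n)
    ys = np.clip(np.round(p0[0] + t * (p1[0] - p0[0])).astype(int), 0, img.shape[0] - 1)
    xs = np.clip(np.round(p0[1] + t * (p1[1] - p0[1])).astype(int), 0, img.shape[1] - 1)
    img[ys, xs] = value


def _branches(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Recursive branching stems growing from the bottom edge."""
    img = np.full((h, w), 0.10)

    def grow(p0, angle: float, length: float, depth: int) -> None:
        if depth == 0 or length < 1.5:
            return
        p1 = (p0[0] - length * np.cos(angle), p0[1] + length * np.sin(angle))
        _draw_segment(img, p0, p1, rng.uniform(0.7, 0.95))
        for _ in range(int(rng.integers(2, 4))):
            grow(p1, angle + rng.uniform(-0.7, 0.7), length * rng.uniform(0.55, 0.8), depth - 1)

    for _ in range(int(rng.integers(2, 4))):
        root = (h - 1.0, rng.uniform(0.2, 0.8) * w)
        grow(root, rng.uniform(-0.4, 0.4), 0.4 * h, depth=4)
    return ndimage.grey_dilation(img, size=(2, 2))


def _speckled(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field plus salt-like speckle."""
    coarse = rng.uniform(0.3, 0.6, size=(4, 4))
    img = ndimage.zoom(coarse, (h / 4, w / 4), order=1)[:h, :w]
    speckle = rng.random((h, w)) < 0.04
    img[speckle] = rng.uniform(0.7, 0.9)
    return img


_FAMILIES = (_grating, _ovals, _branches, _speckled)


def generate_dataset(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> Dataset:
    """``per_class`` images per class, each from its parametric family,
    with additive Gaussian pixel noise; deterministic under the seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    images, labels = [], []
    for label, family in enumerate(_FAMILIES[: spec.n_classes]):
        for _ in range(spec.per_class):
            img = family(h, w, rng)
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(label)
    images = np.asarray(images, dtype=float)[..., None]  # (N, H, W, 1)
    return Dataset(images=images, labels=np.asarray(labels), class_names=spec.class_names)


@dataclass(frozen=True)
class PatchSet:
    """Disjoint grid patches with (parent, row, col) provenance (1-based,
    row-major, top-left = (1, 1)) and inherited labels."""

    patches: np.ndarray  # (n, ph, pw, C)
    provenance: tuple[tuple[int, int, int], ...]
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.patches)


def slice_grid(
    image: np.ndarray, rows: int, cols: int, label: int = 0, parent: int = 0
) -> PatchSet:
    """Slice one image into a rows x cols grid of equal disjoint patches."""
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[..., None]
    h, w = image.shape[:2]
    if h % rows or w % cols:
        raise ValueError(f"image {h}x{w} not divisible by {rows}x{cols} grid")
    ph, pw = h // rows, w // cols
    patches, provenance = [], []
    for r in range(rows):
        for c in range(cols):
            patches.append(image[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw])
            provenance.append((parent, r + 1, c + 1))
    return PatchSet(
        patches=np.asarray(patches),
        provenance=tuple(provenance),
        labels=np.full(rows * cols, label),
    )


def slice_dataset(dataset: Dataset, rows: int, cols: int) -> PatchSet:
    """Slice every image of a dataset; patches inherit the parent label."""
    parts = [
        slice_grid(img, rows, cols, label=int(lab), parent=i)
        for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels))
    ]
    return PatchSet(
        patches=np.concatenate([p.patches for p in parts]),
        provenance=tuple(pr for p in parts for pr in p.provenance),
        labels=np.concatenate([p.labels for p in parts]),
    )


def reassemble(patchset: PatchSet, rows: int, cols: int) -> np.ndarray:
    """Tile the patches of a single parent back into the full image."""
    ph, pw = patchset.patches.shape[1:3]
    c = patchset.patches.shape[3]
    out = np.empty((rows * ph, cols * pw, c))
    for patch, (_, r, col) in zip(patchset.patches, patchset.provenance):
        out[(r - 1) * ph : r * ph, (col - 1) * pw : col * pw] = patch
    return out


@dataclass(frozen=True)
class Overlay:
    image: np.ndarray  # (H, W, 3)
    legend: dict


def overlay(
    image: np.ndarray,
    patch_labels: np.ndarray,
    palette: tuple = DEFAULT_PALETTE,
    class_names: tuple[str, ...] = CLASS_NAMES,
    strength: float = 0.45,
) -> Overlay:
    """Tint each grid cell of ``image`` with its class colour.

    ``patch_labels`` is a (rows, cols) integer array.  Returns the tinted
    RGB image (same spatial dims as the input) plus a class -> colour
    legend.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3 and image.shape[2] == 1:
        image = image[..., 0]
    patch_labels = np.asarray(patch_labels)
    n_used = int(patch_labels.max()) + 1
    if n_used > len(palette):
        raise ValueError(f"palette has {len(palette)} colours for {n_used} classes")
    rows, cols = patch_labels.shape
    h, w = image.shape[:2]
    if h % rows or w % cols:
        raise ValueError("image not divisible by the label grid")
    rgb = np.repeat(image[..., None], 3, axis=2) if image.ndim == 2 else image.copy()
    ph, pw = h // rows, w // cols
    for r in range(rows):
        for c in range(cols):
            colour = np.asarray(palette[int(patch_labels[r, c])])
            cell = rgb[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw]
            cell[:] = (1.0 - strength) * cell + strength * colour
    legend = {class_names[i]: palette[i] for i in range(min(n_used, len(class_names)))}
    return Overlay(image=np.clip(rgb, 0.0, 1.0), legend=legend)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write PNG images plus a ``manifest.csv`` (filename, label) pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
            name = f"img_{i:05d}.png"
            arr = (np.clip(img[..., 0] if img.shape[2] == 1 else img, 0, 1) * 255).astype(
                np.uint8
            )
            iio.imwrite(out_dir / name, arr)
            writer.writerow([name, int(label)])
    return manifest


def load_dataset(
    manifest: str | Path, class_names: tuple[str, ...] = CLASS_NAMES
) -> Dataset:
    """Load a directory of images from its (filename, label) CSV manifest."""
    manifest = Path(manifest)
    images, labels = [], []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            arr = iio.imread(manifest.parent / row["filename"]).astype(float) / 255.0
            if arr.ndim == 2:
                arr = arr[..., None]
            images.append(arr)
            labels.append(int(row["label"]))
    return Dataset(
        images=np.asarray(images), labels=np.asarray(labels), class_names=class_names
    )
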