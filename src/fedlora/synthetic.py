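"""Procedural blood-smear-like image generator.

Emulates the structure a leukemia smear classifier keys on: each image
holds a handful of stained cells (ellipses with a cytoplasm rim and a
textured nucleus) on a noisy plasma background. The four classes differ
in nucleus-to-cytoplasm ratio, chromatin texture roughness, typical cell
count and stain hue — mimicking the progression from benign lymphoid
cells to increasingly blast-like Early Pre-B / Pre-B / Pro-B morphology.
An institution-level stain shift (a per-client RGB offset) models the
staining variation between hospitals that motivates personalization.

Everything is deterministic in (spec, seed); images are uint8 RGB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

DEFAULT_CLASS_NAMES = ("Benign", "Early Pre-B", "Pre-B", "Pro-B")


@dataclass(frozen=True)
class ClassMorphology:
    """Rendering parameters for one cell class."""

    class_id: int
    name: str
    nc_ratio: tuple[float, float]          # nucleus/cell area ratio range
    roughness: float                       # chromatin texture amplitude [0,1]
    cell_count: tuple[int, int]            # cells per image (inclusive range)
    stain_hue: tuple[int, int, int]        # base nucleus stain RGB
    cell_radius: tuple[float, float] = (0.09, 0.14)  # radius / image size

    def __post_init__(self):
        lo, hi = self.nc_ratio
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("nc_ratio range must lie in (0, 1)")


def default_morphologies() -> list[ClassMorphology]:
    """Four classes separated in nucleus size, texture and stain hue."""
    return [
        ClassMorphology(0, "Benign", (0.20, 0.32), 0.04, (2, 4),
                        (185, 130, 200), (0.07, 0.10)),
        ClassMorphology(1, "Early Pre-B", (0.45, 0.58), 0.12, (3, 5),
                        (150, 100, 195), (0.09, 0.12)),
        ClassMorphology(2, "Pre-B", (0.62, 0.75), 0.22, (5, 7),
                        (120, 75, 175), (0.10, 0.13)),
        ClassMorphology(3, "Pro-B", (0.82, 0.94), 0.32, (6, 9),
                        (90, 55, 150), (0.12, 0.16)),
    ]


@dataclass(frozen=True)
class SmearDatasetSpec:
    """What to generate: per-class counts, resolution, stain-shift scale."""

    images_per_class: tuple[int, ...] = (50, 50, 50, 50)
    resolution: int = 224
    client_hue_shift: float = 10.0  # max abs RGB offset per client (uint8 units)
    seed: int = 0
    morphologies: tuple[ClassMorphology, ...] = field(
        default_factory=lambda: tuple(default_morphologies()))

    def __post_init__(self):
        if len(self.images_per_class) != len(self.morphologies):
            raise ValueError("images_per_class must match the number of classes")
        if any(n < 1 for n in self.images_per_class):
            raise ValueError("each class needs at least one image")

    @property
    def class_names(self) -> list[str]:
        return [m.name for m in self.morphologies]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, res: int, sigma: float) -> np.ndarray:
    n = gaussian_filter(rng.standard_normal((res, res)), sigma)
    s = n.std()
    return n / s if s > 0 else n


def generate_image(morph: ClassMorphology, resolution: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one labeled smear image (H, W, 3) uint8."""
    res = resolution
    yy, xx = np.mgrid[0:res, 0:res].astype(np.float32)
    # plasma background: pale with low-frequency mottle and sensor noise
    img = np.empty((res, res, 3), dtype=np.float32)
    base = np.array([232.0, 226.0, 236.0])
    mottle = _smooth_noise(rng, res, res / 16.0)
    for ch in range(3):
        img[..., ch] = base[ch] + 7.0 * mottle + rng.normal(0.0, 2.5, (res, res))

    n_cells = int(rng.integers(morph.cell_count[0], morph.cell_count[1] + 1))
    hue = np.array(morph.stain_hue, dtype=np.float32)
    cyto = np.clip(hue * 0.75 + np.array([80.0, 85.0, 95.0]), 0, 255)
    texture = _smooth_noise(rng, res, 2.0)
    for _ in range(n_cells):
        r_cell = rng.uniform(*morph.cell_radius) * res
        cx = rng.uniform(r_cell, res - r_cell)
        cy = rng.uniform(r_cell, res - r_cell)
        ecc = rng.uniform(0.75, 1.0)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        cell = (u / r_cell) ** 2 + (v / (r_cell * ecc)) ** 2 <= 1.0
        ratio = rng.uniform(*morph.nc_ratio)
        r_nuc = np.sqrt(ratio)  # area ratio -> axis ratio
        nuc = (u / (r_cell * r_nuc)) ** 2 + (v / (r_cell * ecc * r_nuc)) ** 2 <= 1.0
        rim = cell & ~nuc
        for ch in range(3):
            img[..., ch][rim] = cyto[ch] + 6.0 * texture[rim]
            img[..., ch][nuc] = (hue[ch]
                                 + morph.roughness * 90.0 * texture[nuc]
                                 + rng.normal(0.0, 2.0))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(spec: SmearDatasetSpec):
    """Render the full dataset.

    Returns ``(images, labels, manifest)`` where images is a uint8 array
    (N, res, res, 3), labels an int array and the manifest records the
    seed and per-image class for reproducibility.
    """
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for morph, count in zip(spec.morphologies, spec.images_per_class):
        for _ in range(count):
            images.append(generate_image(morph, spec.resolution, rng))
            labels.append(morph.class_id)
    images = np.stack(images)
    labels = np.array(labels, dtype=int)
    manifest = {
        "seed": spec.seed,
        "resolution": spec.resolution,
        "class_names": spec.class_names,
        "images_per_class": list(spec.images_per_class),
        "labels": labels.tolist(),
    }
    return images, labels, manifest


def client_stain_shifts(n_clients: int, magnitude: float, seed: int) -> np.ndarray:
    """One fixed RGB offset per client, uniform in [-magnitude, magnitude]."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-magnitude, magnitude, size=(n_clients, 3)).astype(np.float32)


def apply_stain_shift(images: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Apply an institution-level RGB offset to a stack of uint8 images."""
    out = images.astype(np.float32) + shift[None, None, None, :]
    return np.clip(out, 0, 255).astype(np.uint8)


def normalization_stats(images: np.ndarray):
    """Channel-wise mean/std (on the [0,1] scale) of a training split."""
    x = images.astype(np.float32) / 255.0
    return x.mean(axis=(0, 1, 2)), x.std(axis=(0, 1, 2)) + 1e-8


def to_model_input(images: np.ndarray, mean, std) -> np.ndarray:
    """uint8 HWC stack -> normalized float32 NCHW."""
    x = images.astype(np.float32) / 255.0
    x = (x - np.asarray(mean, dtype=np.float32)) / np.asarray(std, dtype=np.float32)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# Image-folder IO
# ---------------------------------------------------------------------------

def write_imagefolder(images: np.ndarray, labels: np.ndarray, path,
                      class_names=DEFAULT_CLASS_NAMES, manifest: dict | None = None) -> None:
    """class-per-subdirectory layout of PNG files plus a manifest.json."""
    root = Path(path)
    counters = {name: 0 for name in class_names}
    for img, lab in zip(images, labels):
        name = class_names[int(lab)]
        sub = root / name.replace(" ", "_")
        sub.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(sub / f"{counters[name]:05d}.png")
        counters[name] += 1
    meta = dict(manifest or {})
    meta["class_names"] = list(class_names)
    (root / "manifest.json").write_text(json.dumps(meta, indent=1))


def read_imagefolder(path):
    """Inverse of :func:`write_imagefolder`; lossless on pixels and labels."""
    root = Path(path)
    meta = json.loads((root / "manifest.json").read_text())
    class_names = meta["class_names"]
    images, labels = [], []
    for lab, name in enumerate(class_names):
        sub = root / name.replace(" ", "_")
        if not sub.is_dir():
            continue
        for f in sorted(sub.glob("*.png")):
            try:
                with Image.open(f) as im:
                    images.append(np.asarray(im.convert("RGB")))
            except Exception as exc:
                raise IOError(f"unreadable image file {f}") from exc
            labels.append(lab)
    if not images:
        raise IOError(f"no images found under {root}")
    return np.stack(images), np.array(labels, dtype=int), meta
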