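"""Seeded generator of CT-like two-class image datasets.

Positive-class images carry one bright, soft-edged, roughly circular nodule on
a smooth textured background; negative-class images carry background only.
Both classes are corrupted with salt-and-pepper noise so the median-filter
stage has something to remove.  Intensities live in [0, 1] before noise; noise
writes exact 0 (pepper) and 1 (salt) values.

The generator emulates the statistical structure the classifier assumes —
grayscale slices, a present/absent bright lesion, impulse noise — not lung
anatomy; it exists so every pipeline stage is testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class SyntheticSpec:
    """Dataset recipe; the same spec and seed always yield the same dataset.

    ``nodule_contrast`` is the peak intensity offset of the lesion above the
    local background; ``texture_scale`` is the Gaussian correlation length (in
    pixels) of the background texture; ``noise_fraction`` the expected fraction
    of pixels overwritten by salt or pepper.
    """

    n_images: int = 60
    image_size: tuple[int, int] = (64, 64)
    nodule_radius_range: tuple[float, float] = (6.0, 10.0)
    nodule_contrast: float = 0.5
    texture_scale: float = 4.0
    noise_fraction: float = 0.05
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.n_images < 1 or h < 4 or w < 4:
            raise ValueError("need n_images >= 1 and image_size >= 4x4")
        r_min, r_max = self.nodule_radius_range
        if not 0 < r_min <= r_max:
            raise ValueError("nodule radii must be positive with r_min <= r_max")
        if r_max >= min(h, w) / 2:
            raise ValueError(f"r_max {r_max} does not fit inside a {h}x{w} image")
        if not 0.0 <= self.noise_fraction <= 0.2:
            raise ValueError("noise_fraction must lie in [0, 0.2]")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must lie in [0, 1]")


def _background(shape, scale, rng) -> np.ndarray:
    """Smooth random texture in roughly [0.15, 0.55]."""
    rough = rng.random(shape)
    smooth = ndimage.gaussian_filter(rough, sigma=scale, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi > lo:
        smooth = (smooth - lo) / (hi - lo)
    return 0.15 + 0.4 * smooth


def _add_nodule(img, spec: SyntheticSpec, rng) -> np.ndarray:
    h, w = img.shape
    r_min, r_max = spec.nodule_radius_range
    radius = rng.uniform(r_min, r_max)
    margin = int(np.ceil(radius)) + 1
    cy = rng.uniform(margin, h - 1 - margin)
    cx = rng.uniform(margin, w - 1 - margin)
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    # radially symmetric sigmoid edge: soft boundary ~1.5 px wide, no aliasing
    profile = 1.0 / (1.0 + np.exp((dist - radius) / 1.5))
    return np.clip(img + spec.nodule_contrast * profile, 0.0, 1.0)


def salt_and_pepper(img: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Overwrite ~``fraction`` of pixels with exact 0 or 1, half each on average."""
    out = img.copy()
    corrupt = rng.random(img.shape) < fraction
    salt = rng.random(img.shape) < 0.5
    out[corrupt & salt] = 1.0
    out[corrupt & ~salt] = 0.0
    return out


def generate_dataset(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Build the dataset: (images (N,H,W) float64, labels (N,) int, manifest).

    Labels: 1 = nodule present (positive/cancer-like), 0 = background only.
    The class assignment is an exact split (round(n * balance) positives) in a
    seeded random order; the manifest lists a relative file name and label per
    image, matching what :func:`save_dataset` writes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_images
    n_pos = int(round(n * spec.class_balance))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    images = np.empty((n, *spec.image_size))
    for i in range(n):
        img = _background(spec.image_size, spec.texture_scale, rng)
        if labels[i] == 1:
            img = _add_nodule(img, spec, rng)
        images[i] = salt_and_pepper(img, spec.noise_fraction, rng)
    manifest = pd.DataFrame({
        "path": [f"img_{i:05d}.png" for i in range(n)],
        "label": labels,
    })
    return images, labels, manifest


def save_dataset(spec: SyntheticSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the dataset as 8-bit PNGs plus ``manifest.csv``; returns the manifest."""
    from .io import save_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, labels, manifest = generate_dataset(spec)
    for name, img in zip(manifest["path"], images):
        save_png(out / name, img)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def make_separable_tabular(
    n: int = 200,
    dim: int = 2,
    separation: float = 6.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Gaussian clusters ``separation`` standard deviations apart.

    Cluster means sit at ±separation/2 along the first axis, so the Bayes
    decision boundary is the hyperplane x_0 = 0 and the Bayes accuracy is
    Phi(separation / 2) in closed form.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    x = rng.standard_normal((n, dim))
    x[:, 0] += np.where(labels == 1, separation / 2.0, -separation / 2.0)
    return x, labels
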