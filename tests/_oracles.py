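"""Brute-force oracles used across the test suite, independent of the package."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def brute_force_median(image: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Gather each neighborhood explicitly, sort it, take the middle element."""
    m, n = kernel
    pm, pn = m // 2, n // 2
    padded = np.pad(image, ((pm, pm), (pn, pn)), mode="edge")
    out = np.empty_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            window = padded[i : i + m, j : j + n].ravel()
            out[i, j] = np.sort(window)[window.size // 2]
    return out


def scalar_cross_entropy(z: np.ndarray, d: np.ndarray, eps: float = 1e-12) -> float:
    total = 0.0
    for j in range(z.shape[0]):
        for i in range(z.shape[1]):
            total += -d[j, i] * np.log(max(z[j, i], eps))
    return total


def scalar_mse(o: np.ndarray, d: np.ndarray) -> float:
    total = 0.0
    for i in range(o.shape[0]):
        for j in range(o.shape[1]):
            total += (d[i, j] - o[i, j]) ** 2
    return total / o.shape[0]


def scalar_softmax(f: np.ndarray) -> np.ndarray:
    e = np.array([np.exp(v) for v in f])
    return e / e.sum()


def loop_max_pool(x: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Nested-loop block-scan max pooling for a 2-D map."""
    ph, pw = window
    ho, wo = x.shape[0] // ph, x.shape[1] // pw
    out = np.empty((ho, wo))
    for i in range(ho):
        for j in range(wo):
            best = -np.inf
            for a in range(ph):
                for b in range(pw):
                    best = max(best, x[i * ph + a, j * pw + b])
            out[i, j] = best
    return out


def blob_classify(images: np.ndarray, threshold: float = 0.75,
                  min_area: int = 2) -> np.ndarray:
    """Hand-rolled nodule detector: threshold then look for connected blobs.

    Labels an image positive when any above-threshold connected component has
    at least ``min_area`` pixels.  A rendered nodule is a compact disc of tens
    of pixels, so the detector is perfect on clean data; adjacent pairs of
    salt impulses also trip it, which is exactly why impulse noise must be
    median-filtered away first.
    """
    preds = np.empty(images.shape[0], dtype=int)
    for k, img in enumerate(images):
        mask = img >= threshold
        labeled, n_comp = ndimage.label(mask)
        big = 0
        for comp in range(1, n_comp + 1):
            if (labeled == comp).sum() >= min_area:
                big = 1
                break
        preds[k] = big
    return preds
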