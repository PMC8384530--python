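"""Image preprocessing: impulse-noise removal and intensity level balancing.

CT slices arrive with impulse (salt-and-pepper) noise and scanner-dependent
intensity scales.  Before classification each slice is (1) median filtered,
which replaces every pixel by the median of its m-by-n neighborhood and so
removes isolated outliers while preserving edges, (2) min-max normalized onto a
fixed target range, and (3) resized to the network input size.

All functions operate on 2-D float arrays (one grayscale slice) and are
deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

DEFAULT_KERNEL = (5, 5)
DEFAULT_NETWORK_INPUT = (227, 227)


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D grayscale image, got shape {arr.shape}")
    return arr


def median_filter(image: np.ndarray, kernel: tuple[int, int] = DEFAULT_KERNEL) -> np.ndarray:
    """Replace each pixel by the median of its ``kernel``-shaped neighborhood.

    Borders are handled by replicate (edge-clamp) padding so the output has the
    same shape as the input.  Kernel dimensions must be odd so the window has a
    unique center and the median is an order statistic of the window.

    Parameters
    ----------
    image
        2-D grayscale intensity raster.
    kernel
        (m, n) window size; both odd, positive, and no larger than the image.

    Returns
    -------
    Filtered image, same shape and dtype ``float`` as the input.
    """
    arr = _as_image(image)
    m, n = int(kernel[0]), int(kernel[1])
    if m < 1 or n < 1 or m % 2 == 0 or n % 2 == 0:
        raise ValueError(f"kernel dimensions must be odd positive integers, got {kernel}")
    if m > arr.shape[0] or n > arr.shape[1]:
        raise ValueError(f"kernel {kernel} larger than image {arr.shape}")
    return ndimage.median_filter(arr, size=(m, n), mode="nearest")


def min_max_normalize(
    image: np.ndarray,
    a_new: float = 0.0,
    b_new: float = 1.0,
    *,
    on_constant: str = "raise",
) -> np.ndarray:
    """Affinely rescale intensities so min maps to ``a_new`` and max to ``b_new``.

    Computes ``a_new + (b_new - a_new) / (b - a) * (I - a)`` with ``a = min(I)``
    and ``b = max(I)``.  The map is invariant to positive affine transforms of
    the input, so scanner gain and offset drop out.

    Parameters
    ----------
    on_constant
        A constant image has ``a == b`` and no well-defined rescaling.
        ``"raise"`` (default) raises :class:`ValueError`; ``"fill"`` returns an
        all-``a_new`` image instead.
    """
    arr = _as_image(image)
    if not a_new < b_new:
        raise ValueError(f"require a_new < b_new, got ({a_new}, {b_new})")
    a = arr.min()
    b = arr.max()
    if a == b:
        if on_constant == "fill":
            return np.full_like(arr, float(a_new))
        raise ValueError("constant image: min == max leaves the rescaling undefined")
    return a_new + (b_new - a_new) / (b - a) * (arr - a)


def resize(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinearly resample ``image`` to ``target`` (H, W).

    Anti-aliasing (Gaussian prefilter) is applied when downsampling.  Both the
    prefilter and bilinear interpolation are convex combinations of input
    pixels, so output intensities stay within the input's value range; the
    result is clipped to that range to absorb floating-point round-off.
    Resizing to the input's own shape returns an exact copy.
    """
    arr = _as_image(image)
    h, w = int(target[0]), int(target[1])
    if h < 1 or w < 1:
        raise ValueError(f"target shape must be positive, got {target}")
    if (h, w) == arr.shape:
        return arr.copy()
    out = _skimage_resize(arr, (h, w), order=1, mode="edge", preserve_range=True,
                          anti_aliasing=(h < arr.shape[0] or w < arr.shape[1]))
    return np.clip(out, arr.min(), arr.max())


def preprocess_image(
    image: np.ndarray,
    kernel: tuple[int, int] = DEFAULT_KERNEL,
    a_new: float = 0.0,
    b_new: float = 1.0,
    size: tuple[int, int] = DEFAULT_NETWORK_INPUT,
) -> np.ndarray:
    """Full preprocessing chain: median filter, min-max normalize, resize.

    Order is fixed: denoise first (so impulses do not distort the min/max),
    then balance levels, then resample to the classifier input size.
    Constant images (blank slices) are mapped to all-``a_new``.
    """
    out = median_filter(image, kernel)
    out = min_max_normalize(out, a_new, b_new, on_constant="fill")
    return resize(out, size)


def preprocess_stack(images: np.ndarray, **kwargs) -> np.ndarray:
    """Apply :func:`preprocess_image` to every slice of an (N, H, W) stack."""
    return np.stack([preprocess_image(img, **kwargs) for img in images])
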