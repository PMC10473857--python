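"""Scene preprocessing: gray conversion, Gaussian denoising, Otsu
binarization and impurity removal.

The product of this stage is a clean binary foreground mask of the grains,
ready for connected-region triage.  The backlit stage makes grains dark on a
bright background, so the default binarization polarity is
``dark_foreground``.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter

from .synthetic_scenes import MultiChannelImage

#: default gray-conversion weights: ITU-R 601 luminance on R, G, B; the NIR
#: planes feed classification, not segmentation.
DEFAULT_GRAY_WEIGHTS = (0.299, 0.587, 0.114, 0.0, 0.0)

Polarity = Literal["dark_foreground", "bright_foreground"]


class DegenerateHistogramError(ValueError):
    """Otsu thresholding requested on a constant image."""


def to_gray(image: MultiChannelImage, channel_weights=DEFAULT_GRAY_WEIGHTS) -> np.ndarray:
    """Pixelwise weighted channel sum, rounded half-up to 8-bit.

    ``channel_weights`` must be nonnegative and sum to 1 (one weight per
    plane, in (R, G, B, NIR1, NIR2) order).
    """
    w = np.asarray(channel_weights, dtype=np.float64)
    if w.shape != (image.planes.shape[2],):
        raise ValueError(f"expected {image.planes.shape[2]} weights, got {w.shape}")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("channel weights must be nonnegative and sum to 1")
    gray = image.planes.astype(np.float64) @ w
    return np.floor(gray + 0.5).astype(np.uint8)


def gaussian_denoise(gray: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Convolve with a truncated sampled Gaussian (radius ``ceil(3*sigma)``).

    Borders are handled by reflection; ``sigma = 0`` returns the input
    unchanged.  Output is rounded half-up back to uint8.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return gray.copy()
    radius = math.ceil(3.0 * sigma)
    out = gaussian_filter(gray.astype(np.float64), sigma, mode="reflect", radius=radius)
    return np.floor(out + 0.5).astype(np.uint8)


def otsu_threshold_from_hist(hist: np.ndarray) -> int:
    """Between-class-variance argmax over thresholds t = 0..n_bins-1.

    Classes are bins ``<= t`` vs ``> t``; ties on the variance go to the
    smallest t.  Raises :class:`DegenerateHistogramError` if fewer than two
    bins are populated.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than two populated bins")
    total = hist.sum()
    p = hist / total
    omega0 = np.cumsum(p)
    mu_cum = np.cumsum(p * np.arange(hist.size))
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
    sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    return int(np.argmax(sigma_b))  # first occurrence = smallest t


def binarize_otsu(
    gray: np.ndarray, polarity: Polarity = "dark_foreground"
) -> tuple[np.ndarray, int]:
    """Otsu binarization over the 256-bin intensity histogram.

    Foreground is ``gray <= t*`` for ``dark_foreground`` and ``gray > t*``
    otherwise.  Returns ``(mask, t*)``.
    """
    if polarity not in ("dark_foreground", "bright_foreground"):
        raise ValueError(f"unknown polarity {polarity!r}")
    g = np.asarray(gray)
    if g.dtype != np.uint8:
        raise ValueError("binarize_otsu expects an 8-bit image")
    hist = np.bincount(g.ravel(), minlength=256)
    t = otsu_threshold_from_hist(hist)
    if polarity == "dark_foreground":
        mask = g <= t
    else:
        mask = g > t
    return mask, t


def remove_small_components(
    mask: np.ndarray, min_area: int, connectivity: int = 8
) -> np.ndarray:
    """Drop connected foreground components with area < ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    if min_area == 0:
        return mask.copy()
    structure = np.ones((3, 3), bool) if connectivity == 8 else None
    lab, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


def foreground_mask(
    image: MultiChannelImage,
    sigma: float = 1.0,
    min_area: int | None = None,
    channel_weights=DEFAULT_GRAY_WEIGHTS,
    polarity: Polarity = "dark_foreground",
    connectivity: int = 8,
    min_contrast: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Full preprocessing chain; returns (mask, denoised gray, threshold).

    ``min_area`` defaults to 5% of the package's default expected grain area
    when not given (callers with a :class:`SceneSpec` should pass
    ``0.05 * spec.expected_grain_area``).  When the two Otsu classes are
    separated by less than ``min_contrast`` gray levels the image is
    declared object-free (Otsu on a unimodal histogram would otherwise
    bisect the background noise): the returned mask is empty.
    """
    gray = to_gray(image, channel_weights)
    den = gaussian_denoise(gray, sigma)
    mask, t = binarize_otsu(den, polarity)
    fg_vals, bg_vals = den[mask], den[~mask]
    if fg_vals.size == 0 or bg_vals.size == 0 or (
        abs(float(fg_vals.mean()) - float(bg_vals.mean())) < min_contrast
    ):
        mask = np.zeros_like(mask)
    if min_area is None:
        from .synthetic_scenes import SceneSpec

        min_area = int(round(0.05 * SceneSpec().expected_grain_area))
    mask = remove_small_components(mask, min_area, connectivity)
    return mask, den, t
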