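"""Standardization of raw en face angiograms before binarization.

The quantitative pipeline crops each scan to its central square (peripheral
signal falls off with distance from the fovea), stretches the brightness
histogram to a common range, and rescales intensities to a target mean and
standard deviation so that images from different sessions are thresholded
on a comparable brightness scale.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .image import EnFaceImage

__all__ = [
    "central_crop",
    "contrast_stretch",
    "normalize_histogram",
    "NormalizationResult",
    "standardize",
]


def central_crop(image: EnFaceImage, fraction: float = 0.5) -> EnFaceImage:
    """Centered square crop retaining ``fraction`` of each linear dimension.

    The default 0.5 keeps the central square at 50% of the image size
    (a 6 x 6 mm scan becomes its central 3 x 3 mm).  The cropped side is
    ``floor(fraction * side)`` per axis; when the discarded margin is odd
    the extra pixel is dropped from the bottom/right.

    Raises
    ------
    ValueError
        If ``fraction`` is outside (0, 1] or the crop would be empty.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    h, w = image.shape
    ch, cw = int(np.floor(fraction * h)), int(np.floor(fraction * w))
    if ch < 1 or cw < 1:
        raise ValueError("crop fraction leaves no pixels")
    y0 = (h - ch) // 2
    x0 = (w - cw) // 2
    return image.with_pixels(image.pixels[y0:y0 + ch, x0:x0 + cw])


def contrast_stretch(image: EnFaceImage, low_pct: float = 0.5,
                     high_pct: float = 99.5) -> EnFaceImage:
    """Linearly map the [low_pct, high_pct] intensity percentiles to [0, 255].

    Intensities outside the percentile window are clipped.  The slightly
    inset default percentiles make the stretch robust to isolated speckle
    extremes.  Constant images are returned unchanged (the map would be
    undefined).
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    px = image.astype_float()
    lo, hi = np.percentile(px, [low_pct, high_pct])
    if hi <= lo:  # flat histogram in the window; nothing to stretch
        return image
    out = np.clip((px - lo) / (hi - lo) * 255.0, 0, 255)
    return image.with_pixels(np.rint(out).astype(np.uint8))


class NormalizationResult(NamedTuple):
    """Output of :func:`normalize_histogram`."""

    image: EnFaceImage
    achieved_mean: float
    achieved_sd: float
    degenerate: bool  # True when the input had zero variance


def normalize_histogram(image: EnFaceImage, target_mean: float = 128.0,
                        target_sd: float = 25.0) -> NormalizationResult:
    """Affine intensity rescale to a standard brightness histogram.

    The sample mean and SD are mapped onto ``(target_mean, target_sd)``
    before rounding and clipping to [0, 255]; the achieved post-clip
    statistics are reported alongside the image.  A zero-variance input
    cannot be rescaled and is returned as a constant image at
    ``target_mean`` with ``degenerate=True``.
    """
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    px = image.astype_float()
    mu, sd = px.mean(), px.std()
    if sd == 0:
        out = np.full(image.shape, np.clip(round(target_mean), 0, 255),
                      dtype=np.uint8)
        im = image.with_pixels(out)
        return NormalizationResult(im, float(out.mean()), 0.0, True)
    out = np.clip((px - mu) / sd * target_sd + target_mean, 0, 255)
    out = np.rint(out).astype(np.uint8)
    im = image.with_pixels(out)
    return NormalizationResult(im, float(out.mean()), float(out.std()), False)


def standardize(image: EnFaceImage, *, fraction: float = 0.5,
               low_pct: float = 0.5, high_pct: float = 99.5,
               target_mean: float = 128.0,
               target_sd: float = 25.0) -> EnFaceImage:
    """Full standardization chain: crop, then stretch, then normalize."""
    im = central_crop(image, fraction)
    im = contrast_stretch(im, low_pct, high_pct)
    return normalize_histogram(im, target_mean, target_sd).image
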