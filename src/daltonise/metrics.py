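"""Quantitative evaluation: gamut pixel fraction, PSNR, paired comparison.

GPF (gamut pixel fraction) is the fraction of pixels with any channel at
the gamut boundary (0 or 1); it proxies clipping-induced loss of detail.
PSNR = −10·log10(MSE) for images in [0, 1] measures colour distortion of a
daltonised image relative to the original.  Methods are compared per image
with the two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .image_model import as_colour_image

__all__ = [
    "EPS_BOUNDARY",
    "DegenerateTestError",
    "PairedComparison",
    "gamut_pixel_fraction",
    "psnr",
    "paired_comparison",
]

#: Half an 8-bit quantum: robust to 8-bit round-trips of boundary values.
EPS_BOUNDARY = 1.0 / 510.0


class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass(frozen=True)
class PairedComparison:
    """Result of a paired two-sided Wilcoxon signed-rank comparison."""

    p_value: float
    median_a: float
    median_b: float
    n: int


def gamut_pixel_fraction(
    img: np.ndarray,
    eps: float = EPS_BOUNDARY,
    quantise: bool = False,
) -> float:
    """Fraction of pixels with ANY channel within ``eps`` of 0 or 1.

    With ``quantise`` the image is first rounded to 8 bits and a pixel
    counts when a channel sits exactly at 0 or 255; the default evaluates
    the floating-point image directly.
    """
    img = as_colour_image(img)
    if quantise:
        q = np.floor(np.clip(img, 0, 1) * 255.0 + 0.5)
        at_bound = (q <= 0) | (q >= 255)
    else:
        at_bound = (img <= eps) | (img >= 1.0 - eps)
    return float(at_bound.any(axis=2).mean())


def psnr(image: np.ndarray, reference: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for images in [0, 1] (peak = 1).

    MSE is averaged over pixels and channels; identical images give +inf.
    """
    image = as_colour_image(image)
    reference = as_colour_image(reference)
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reference.shape}")
    mse = float(np.mean((image - reference) ** 2))
    if mse == 0.0:
        return float("inf")
    return -10.0 * np.log10(mse)


def paired_comparison(
    values_a: Sequence[float], values_b: Sequence[float]
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on per-image paired metrics.

    Exact null distribution for n ≤ 25, normal approximation above.
    Raises :class:`DegenerateTestError` when every pair is tied.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if np.all(a == b):
        raise DegenerateTestError("all paired differences are zero")
    method = "exact" if len(a) <= 25 else "approx"
    result = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return PairedComparison(
        p_value=float(result.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n=len(a),
    )
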