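"""Image representation, file I/O and gamut operations.

Images are plain ``float64`` numpy arrays of shape ``(H, W, 3)`` holding
sRGB-encoded intensities in ``[0, 1]``.  All processing in this package
operates directly on these encoded values — no linearisation is applied,
matching the convention of the observer-model matrices, which are defined
on encoded RGB.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "as_colour_image",
    "read_image",
    "write_image",
    "gamut_clip",
    "quantise8",
]


class ImageFormatError(ValueError):
    """Raised for images with an unsupported layout (e.g. >4 channels)."""


def as_colour_image(data: np.ndarray) -> np.ndarray:
    """Coerce an array to a validated H×W×3 float64 colour image.

    Greyscale (H×W) input is promoted to three equal channels; an alpha
    channel is dropped.  Values are not rescaled or clipped.
    """
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3:
        raise ImageFormatError(f"expected 2-D or 3-D array, got shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ImageFormatError(f"unsupported channel count {arr.shape[2]}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ImageFormatError("image must have at least one pixel")
    return arr


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8- or 16-bit RGB image (PNG, PPM, ...) as floats in [0, 1].

    Values are scaled by the bit-depth maximum of the stored integer type.
    No gamma transform is applied.
    """
    raw = iio.imread(path)
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        scale = 1.0
    else:
        raise ImageFormatError(f"unsupported sample type {raw.dtype}")
    return as_colour_image(raw.astype(np.float64) / scale)


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an image as 8-bit RGB (format chosen from the file extension).

    Values are clipped to [0, 1] first and quantised with
    round-half-away-from-zero: ``floor(255 v + 0.5)``.  This rounding rule
    is fixed so gamut-pixel counts on written files are reproducible.
    """
    img = gamut_clip(as_colour_image(img))
    quantised = np.floor(img * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(path, quantised)


def quantise8(img: np.ndarray) -> np.ndarray:
    """Round to the 8-bit grid (multiples of 1/255), staying in float.

    This is the value a written PNG would carry; metrics computed on
    quantised images match metrics computed on the files.
    """
    img = gamut_clip(as_colour_image(img))
    return np.floor(img * 255.0 + 0.5) / 255.0


def gamut_clip(img: np.ndarray) -> np.ndarray:
    """Project onto the RGB gamut by clamping each channel to [0, 1].

    This is the gamut projection used both in simple daltonisation and as
    the per-step constraint of the diffusion solver.  Idempotent and
    non-expansive per channel.
    """
    return np.clip(img, 0.0, 1.0)
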