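"""Colour-direction analysis and the simple daltonisation estimate.

The information a CVD observer loses when viewing image ``u0`` is the
difference field ``d0 = u0 - s(u0)``.  An uncentred PCA of ``d0`` gives the
principal lost-difference direction ``p1``; Gram–Schmidt against the grey
axis then yields the orthonormal colour-space triplet

* ``el`` — lightness (grey) axis,
* ``ed`` — lost-difference direction,
* ``ec`` — remaining direction of maximally visible chroma change.

Rotating the lost component into ``ec`` gives both the closed-form *simple*
daltonisation  ``us = clip(u0 + (u0·ed) ec)``  and the modified gradient
tensor  ``G = ∇u0 + (∇u0·ed) ec``  that the diffusion solver reintegrates.

The PCA is uncentred (second-moment matrix of the raw difference vectors):
``d0`` measures displacement from the simulation surface, so the meaningful
axis passes through the origin, and centring would misbehave on images
where most pixels have ``d0 ≈ 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cvd import SimulationBackend, simulate
from .image_model import as_colour_image, gamut_clip

__all__ = [
    "DegenerateDifferenceError",
    "DirectionBasis",
    "GREY_AXES",
    "lost_difference",
    "principal_difference_direction",
    "build_basis",
    "observer_basis",
    "simple_daltonise",
    "spatial_gradient",
    "modified_gradient",
]

#: Selectable grey axes (unnormalised): the RGB-cube diagonal, or the
#: direction orthogonal to the sRGB constant-luminance plane.
GREY_AXES = {
    "flat": np.array([1.0, 1.0, 1.0]),
    "luminance": np.array([0.2126, 0.7152, 0.0722]),
}

GreyAxis = Literal["flat", "luminance"]

#: Below this max-pixel ||d0|| the observer is treated as colour normal.
EPS_DEGENERATE = 1e-6

#: Angular tolerance (radians) under which p1 counts as parallel to el.
EPS_PARALLEL = 1e-6


class DegenerateDifferenceError(ValueError):
    """Lost-information field is (near) zero or purely achromatic.

    Callers map this to "return the original image unchanged": there is
    nothing invisible to rotate into view.
    """


@dataclass(frozen=True)
class DirectionBasis:
    """Orthonormal colour-space triplet (el, ed, ec)."""

    el: np.ndarray
    ed: np.ndarray
    ec: np.ndarray

    def __post_init__(self) -> None:
        for name, v in (("el", self.el), ("ed", self.ed), ("ec", self.ec)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-10:
                raise ValueError(f"{name} is not a unit vector")
        for a, b in ((self.el, self.ed), (self.el, self.ec), (self.ed, self.ec)):
            if abs(float(a @ b)) > 1e-10:
                raise ValueError("basis vectors are not orthogonal")

    def flipped(self) -> "DirectionBasis":
        """Same basis with the sign of ec reversed (the other recolour hue)."""
        return DirectionBasis(self.el, self.ed, -self.ec)


def lost_difference(img: np.ndarray, observer: SimulationBackend) -> np.ndarray:
    """Per-pixel lost information d0 = u0 - s(u0); shape (H, W, 3)."""
    img = as_colour_image(img)
    return img - simulate(img, observer)


def principal_difference_direction(d0: np.ndarray) -> np.ndarray:
    """First principal direction of the difference field (uncentred PCA).

    Returns the unit 3-vector maximising ``sum_pixels (d0 · p)**2``, i.e.
    the dominant eigenvector of the 3×3 second-moment matrix ``d0ᵀ d0``.
    The sign is fixed so the largest-magnitude component is positive.

    Raises
    ------
    DegenerateDifferenceError
        If every pixel's difference is below the degeneracy threshold.
    """
    vecs = np.asarray(d0, dtype=np.float64).reshape(-1, 3)
    norms = np.linalg.norm(vecs, axis=1)
    if norms.max(initial=0.0) < EPS_DEGENERATE:
        raise DegenerateDifferenceError("difference image is zero: nothing is lost")
    moment = vecs.T @ vecs
    eigvals, eigvecs = np.linalg.eigh(moment)
    p1 = eigvecs[:, np.argmax(eigvals)]
    # deterministic sign: largest-|component| positive
    if p1[np.argmax(np.abs(p1))] < 0:
        p1 = -p1
    return p1


def build_basis(p1: np.ndarray, grey_axis: GreyAxis = "luminance") -> DirectionBasis:
    """Gram–Schmidt basis from the grey axis and the lost direction p1.

    ``el`` is the normalised grey axis, ``ed`` the component of ``p1``
    orthogonal to it, and ``ec = el × ed`` (right-handed, no further sign
    flip; either sign of ec yields equal-magnitude visible contrast, only
    the hue of the recolouring differs).

    Raises
    ------
    DegenerateDifferenceError
        If ``p1`` is parallel to the grey axis (the lost information is
        purely achromatic, so no chroma rotation can expose it).
    """
    el = GREY_AXES[grey_axis] / np.linalg.norm(GREY_AXES[grey_axis])
    p1 = np.asarray(p1, dtype=np.float64)
    p1 = p1 / np.linalg.norm(p1)
    residual = p1 - (p1 @ el) * el
    # |residual| = sin(angle between p1 and el)
    if np.linalg.norm(residual) < EPS_PARALLEL:
        raise DegenerateDifferenceError("lost information is purely achromatic")
    ed = residual / np.linalg.norm(residual)
    ec = np.cross(el, ed)
    ec = ec / np.linalg.norm(ec)
    return DirectionBasis(el=el, ed=ed, ec=ec)


def observer_basis(
    img: np.ndarray,
    observer: SimulationBackend,
    grey_axis: GreyAxis = "luminance",
) -> DirectionBasis:
    """Direction basis for this (image, observer) pair.

    Convenience composition: lost difference → PCA → Gram–Schmidt.
    """
    d0 = lost_difference(img, observer)
    return build_basis(principal_difference_direction(d0), grey_axis)


def simple_daltonise(
    img: np.ndarray,
    observer: SimulationBackend,
    grey_axis: GreyAxis = "luminance",
    flip_ec: bool = False,
) -> np.ndarray:
    """Closed-form daltonisation  us = clip(u0 + (u0·ed) ec).

    Fast and halo-free, but the gamut clipping can destroy texture in
    saturated regions; it is also the initial value for the diffusion
    methods.  Degenerate observers (greyscale image, alpha = 0, purely
    achromatic loss) return the input unchanged.
    """
    img = as_colour_image(img)
    try:
        basis = observer_basis(img, observer, grey_axis)
    except DegenerateDifferenceError:
        return img.copy()
    if flip_ec:
        basis = basis.flipped()
    projection = img @ basis.ed
    return gamut_clip(img + projection[:, :, None] * basis.ec)


def spatial_gradient(img: np.ndarray) -> np.ndarray:
    """Forward-difference spatial gradient; shape (H, W, 2, 3).

    ``grad[..., 0, :]`` is the difference along rows (u[i+1,j] - u[i,j])
    and ``grad[..., 1, :]`` along columns, with zero (Neumann) boundary at
    the last row/column.  The divergence in the solver module is the exact
    negative adjoint of this operator.
    """
    img = np.asarray(img, dtype=np.float64)
    grad = np.zeros(img.shape[:2] + (2, 3))
    grad[:-1, :, 0, :] = img[1:, :, :] - img[:-1, :, :]
    grad[:, :-1, 1, :] = img[:, 1:, :] - img[:, :-1, :]
    return grad


def modified_gradient(img: np.ndarray, basis: DirectionBasis) -> np.ndarray:
    """Modified gradient tensor G = ∇u0 + (∇u0·ed) ec.

    The dot product contracts the colour index, leaving a per-pixel,
    per-spatial-direction scalar that is re-expanded along ec: the lost
    chromatic edge content rotated into the visible direction.
    """
    grad = spatial_gradient(img)
    projection = grad @ basis.ed  # (H, W, 2)
    return grad + projection[..., None] * basis.ec
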