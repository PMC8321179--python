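"""Parametrised colour-vision-deficiency observer model.

A CVD observer is modelled by a 3×3 matrix acting directly on encoded RGB
values, blended with the identity by a severity ``alpha``:

    s(u) = alpha * M u + (1 - alpha) * u

``alpha = 0`` is a colour-normal observer, ``0 < alpha < 1`` an anomalous
trichromat, ``alpha = 1`` a dichromat.  Two dichromat matrices are
provided: red–green (``"rg"``, covering protan/deutan-type confusion) and
blue–yellow (``"by"``, tritan-type).  Both have rows summing to one, so
achromatic colours are fixed points and the simulation maps the gamut into
itself — no clipping is ever needed after simulation.

The daltonisation pipeline only requires an image → image simulation, so
any object with a ``simulate(img)`` method (e.g. a cone-space dichromat
projection) can stand in for :class:`Observer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .image_model import as_colour_image

__all__ = [
    "M_RG",
    "M_BY",
    "Observer",
    "SimulationBackend",
    "make_observer",
    "simulate",
]

M_RG = np.array(
    [
        [0.5, 0.5, 0.0],
        [0.5, 0.5, 0.0],
        [0.0, 0.0, 1.0],
    ]
)
"""Red–green dichromat matrix (projects onto the red=green plane)."""

M_BY = np.array(
    [
        [0.5, 0.0, 0.5],
        [0.0, 0.5, 0.5],
        [0.25, 0.25, 0.5],
    ]
)
"""Blue–yellow dichromat matrix."""

_MATRICES = {"rg": M_RG, "by": M_BY}


@runtime_checkable
class SimulationBackend(Protocol):
    """Anything that maps an RGB image to the CVD percept image."""

    def simulate(self, img: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class Observer:
    """CVD observer: deficiency class plus severity.

    Parameters
    ----------
    kind:
        ``"rg"`` (red–green) or ``"by"`` (blue–yellow).
    alpha:
        Severity in [0, 1].
    """

    kind: str
    alpha: float
    matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        if kind not in _MATRICES:
            raise ValueError(f"unknown deficiency kind {self.kind!r}; expected 'rg' or 'by'")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"severity alpha must lie in [0, 1], got {self.alpha}")
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "matrix", _MATRICES[kind])

    @property
    def blended_matrix(self) -> np.ndarray:
        """The effective matrix alpha*M + (1-alpha)*I."""
        return self.alpha * self.matrix + (1.0 - self.alpha) * np.eye(3)

    def simulate(self, img: np.ndarray) -> np.ndarray:
        """Per-pixel affine blend s(u) = alpha*M u + (1-alpha) u."""
        img = as_colour_image(img)
        return img @ self.blended_matrix.T


def make_observer(kind: str, alpha: float) -> Observer:
    """Build an :class:`Observer`; raises ``ValueError`` for alpha ∉ [0, 1]."""
    return Observer(kind=kind, alpha=alpha)


def simulate(img: np.ndarray, observer: SimulationBackend) -> np.ndarray:
    """Simulate what ``observer`` perceives when viewing ``img``."""
    return observer.simulate(img)
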