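"""Gradient-field reintegration by explicit diffusion.

Given the modified gradient tensor G built from the original image, the
daltonised image is the minimiser of ``∫ |∇u - G|²`` over the gamut,
found by explicit-Euler gradient descent on

    isotropic:    du/dt = ∇·(∇u - G)
    anisotropic:  du/dt = ∇·[D (∇u - G)]

where D is a per-pixel symmetric positive-definite 2×2 diffusion tensor
derived from the structure tensor of the *original* image and frozen for
the whole iteration ("local linear").  D throttles diffusion across strong
edges, which is what removes the halo artefacts of the isotropic scheme.
The gamut constraint is enforced by clipping after every step (projected
gradient descent), and the simple daltonisation serves as the initial
value, which cuts convergence time dramatically compared to starting from
the original image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import (
    DegenerateDifferenceError,
    GreyAxis,
    modified_gradient,
    observer_basis,
    simple_daltonise,
    spatial_gradient,
)
from .cvd import SimulationBackend
from .image_model import as_colour_image, gamut_clip

__all__ = [
    "SolverConfig",
    "Diagnostics",
    "NumericalInstabilityError",
    "structure_tensor",
    "diffusivity",
    "diffusion_tensor",
    "divergence",
    "reintegrate",
    "daltonise",
    "isotropic_daltonise",
    "anisotropic_daltonise",
]


class NumericalInstabilityError(FloatingPointError):
    """Non-finite values appeared during the explicit iteration."""


@dataclass(frozen=True)
class SolverConfig:
    """Explicit-diffusion solver parameters.

    Parameters
    ----------
    kappa:
        Diffusivity scale in d(λ) = 1/(1 + κλ²).  The default 1e4 places
        the transition of d at gradient magnitudes of order 1e-2, i.e.
        8-bit edges of a few tens of levels under unit-spaced forward
        differences on [0, 1] data.
    dt:
        Explicit Euler time step.  Must satisfy dt ≤ 0.25 (the 2-D
        stability bound, since the diffusion tensor spectrum is ≤ 1);
        default 0.24, just under the bound.
    tol:
        Stop when the max-norm update per unit time, max|Δu|/dt, falls
        below this.
    max_iter:
        Iteration cap.
    record_energy:
        If set, the diagnostics carry the per-iteration energy trace
        Σ ‖∇u - G‖²_F.
    smoothing_sigma:
        Optional Gaussian pre-smoothing radius (pixels) for the structure
        tensor; 0 disables it (default).
    """

    kappa: float = 1e4
    dt: float = 0.24
    tol: float = 1e-4
    max_iter: int = 1000
    record_energy: bool = False
    smoothing_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 < self.dt <= 0.25:
            raise ValueError("dt must lie in (0, 0.25] for explicit stability")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be non-negative")


@dataclass
class Diagnostics:
    """Solver run record: iteration count, final residual, traces.

    ``updates`` holds max|Δu|/dt per iteration; ``energy`` holds the
    residual energy Σ‖∇u−G‖²_F per iteration when recording is enabled.
    """

    iterations: int = 0
    final_update: float = float("nan")
    energy: list[float] = field(default_factory=list)
    updates: list[float] = field(default_factory=list)


def structure_tensor(
    img: np.ndarray,
    mode: Literal["di_zenzo", "summed"] = "di_zenzo",
    smoothing_sigma: float = 0.0,
) -> np.ndarray:
    """Per-pixel 2×2 structure tensor of a colour image; shape (H, W, 2, 2).

    ``di_zenzo`` (default) is the standard multichannel tensor
    S_ij = Σ_μ (∂u_μ/∂x_i)(∂u_μ/∂x_j).  ``summed`` first sums the
    gradient over channels and takes the outer product — kept only for
    comparison, as a literal reading of the double-sum notation.
    Symmetric positive semi-definite in either mode.
    """
    grad = spatial_gradient(img)  # (H, W, 2, 3)
    if mode == "di_zenzo":
        S = np.einsum("hwic,hwjc->hwij", grad, grad)
    elif mode == "summed":
        summed = grad.sum(axis=3)  # (H, W, 2)
        S = summed[..., :, None] * summed[..., None, :]
    else:
        raise ValueError(f"unknown structure-tensor mode {mode!r}")
    if smoothing_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for i in range(2):
            for j in range(2):
                S[:, :, i, j] = gaussian_filter(S[:, :, i, j], smoothing_sigma)
    return S


def diffusivity(lam: np.ndarray | float, kappa: float) -> np.ndarray | float:
    """Nonlinear diffusion coefficient d(λ) = 1/(1 + κλ²), in (0, 1]."""
    lam = np.asarray(lam, dtype=np.float64)
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalue argument must be non-negative")
    lam = np.maximum(lam, 0.0)
    out = 1.0 / (1.0 + kappa * lam**2)
    return float(out) if out.ndim == 0 else out


def diffusion_tensor(S: np.ndarray, kappa: float) -> np.ndarray:
    """Diffusion tensor with S's eigenvectors and eigenvalues d(λ±).

    D = E diag(d(λ+), d(λ−)) Eᵀ per pixel; symmetric positive definite
    with spectrum in (0, 1], and commuting with S.
    """
    eigvals, eigvecs = np.linalg.eigh(S)
    d = diffusivity(eigvals, kappa)
    return np.einsum("...ik,...k,...jk->...ij", eigvecs, d, eigvecs)


def _backward_div_1d(p: np.ndarray, axis: int) -> np.ndarray:
    """Negative adjoint of the forward difference along one axis."""
    out = np.zeros_like(p)
    n = p.shape[axis]
    src = np.moveaxis(p, axis, 0)
    dst = np.moveaxis(out, axis, 0)
    dst[0] = src[0]
    dst[1 : n - 1] = src[1 : n - 1] - src[0 : n - 2]
    dst[n - 1] = -src[n - 2]
    return out


def divergence(p: np.ndarray) -> np.ndarray:
    """Discrete divergence of a gradient-shaped field; shape (H, W, 3).

    Exact negative adjoint of :func:`daltonise.core.spatial_gradient`:
    ⟨∇u, p⟩ = −⟨u, ∇·p⟩ for all u, p, which makes the explicit scheme
    dissipate the discrete energy.
    """
    p = np.asarray(p, dtype=np.float64)
    return _backward_div_1d(p[:, :, 0, :], axis=0) + _backward_div_1d(
        p[:, :, 1, :], axis=1
    )


def reintegrate(
    u0: np.ndarray,
    G: np.ndarray,
    mode: Literal["isotropic", "anisotropic"] = "anisotropic",
    init: np.ndarray | None = None,
    cfg: SolverConfig | None = None,
    D: np.ndarray | None = None,
    clip: bool = True,
) -> tuple[np.ndarray, Diagnostics]:
    """Reintegrate the gradient tensor G into an image.

    Explicit Euler iteration ``u ← clip(u + dt ∇·[D(∇u − G)])`` with D the
    identity in isotropic mode and, in anisotropic mode, the frozen
    diffusion tensor of ``u0`` (built here unless passed in).  Stops when
    ``max|Δu|/dt < tol`` or at ``max_iter``.

    Returns the final image and a :class:`Diagnostics` record.
    """
    cfg = cfg or SolverConfig()
    u0 = as_colour_image(u0)
    u = u0.copy() if init is None else as_colour_image(init).copy()
    if mode == "anisotropic" and D is None:
        D = diffusion_tensor(
            structure_tensor(u0, smoothing_sigma=cfg.smoothing_sigma), cfg.kappa
        )
    elif mode == "isotropic":
        D = None
    elif mode != "anisotropic":
        raise ValueError(f"unknown mode {mode!r}")

    if D is not None:
        # unpack the symmetric 2x2 field once; cheaper than einsum per step
        d00 = D[:, :, 0, 0, None]
        d01 = D[:, :, 0, 1, None]
        d11 = D[:, :, 1, 1, None]

    diag = Diagnostics()
    for iteration in range(1, cfg.max_iter + 1):
        residual = spatial_gradient(u) - G
        if cfg.record_energy:
            diag.energy.append(float(np.sum(residual**2)))
        if D is not None:
            r0 = residual[:, :, 0, :]
            r1 = residual[:, :, 1, :]
            residual = np.stack(
                (d00 * r0 + d01 * r1, d01 * r0 + d11 * r1), axis=2
            )
        u_next = u + cfg.dt * divergence(residual)
        if clip:
            u_next = gamut_clip(u_next)
        if not np.all(np.isfinite(u_next)):
            raise NumericalInstabilityError(
                f"non-finite values at iteration {iteration} (dt={cfg.dt})"
            )
        change = float(np.max(np.abs(u_next - u))) / cfg.dt
        u = u_next
        diag.iterations = iteration
        diag.final_update = change
        diag.updates.append(change)
        if change < cfg.tol:
            break
    return u, diag


def daltonise(
    img: np.ndarray,
    observer: SimulationBackend,
    method: Literal["simple", "isotropic", "anisotropic"] = "anisotropic",
    cfg: SolverConfig | None = None,
    grey_axis: GreyAxis = "luminance",
    flip_ec: bool = False,
) -> tuple[np.ndarray, Diagnostics]:
    """Full daltonisation pipeline for one image and observer.

    All three methods share the direction basis computed once from the
    original image: ``simple`` returns the closed-form estimate directly;
    ``isotropic`` and ``anisotropic`` use it as the initial condition and
    reintegrate the modified gradient tensor.  Degenerate cases (no lost
    information, or purely achromatic loss) return the input unchanged.
    """
    if method not in ("simple", "isotropic", "anisotropic"):
        raise ValueError(f"unknown method {method!r}")
    img = as_colour_image(img)
    cfg = cfg or SolverConfig()
    try:
        basis = observer_basis(img, observer, grey_axis)
    except DegenerateDifferenceError:
        return img.copy(), Diagnostics(iterations=0, final_update=0.0)
    if flip_ec:
        basis = basis.flipped()
    projection = img @ basis.ed
    us = gamut_clip(img + projection[:, :, None] * basis.ec)
    if method == "simple":
        return us, Diagnostics(iterations=0, final_update=0.0)
    if method not in ("isotropic", "anisotropic"):
        raise ValueError(f"unknown method {method!r}")
    G = modified_gradient(img, basis)
    return reintegrate(img, G, mode=method, init=us, cfg=cfg)


def isotropic_daltonise(
    img: np.ndarray,
    observer: SimulationBackend,
    cfg: SolverConfig | None = None,
    grey_axis: GreyAxis = "luminance",
    flip_ec: bool = False,
) -> np.ndarray:
    """Isotropic gradient-domain daltonisation (halo-prone comparison method)."""
    return daltonise(img, observer, "isotropic", cfg, grey_axis, flip_ec)[0]


def anisotropic_daltonise(
    img: np.ndarray,
    observer: SimulationBackend,
    cfg: SolverConfig | None = None,
    grey_axis: GreyAxis = "luminance",
    flip_ec: bool = False,
) -> np.ndarray:
    """Halo-free anisotropic gradient-domain daltonisation."""
    return daltonise(img, observer, "anisotropic", cfg, grey_axis, flip_ec)[0]
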