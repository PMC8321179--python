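"""Seeded synthetic test images with CVD-confusable chromatic contrast.

Real evaluation sets for daltonisation are colourful photographs with
dominant red–green or blue–yellow contrast.  This module generates small
deterministic stand-ins with the same statistical structure: pairs of
colours that a simulated dichromat cannot tell apart, arranged as Ishihara
style dot plates, hard chroma edges, smooth ramps, and noise textures.

Confusable palettes are built by construction, not by trial: a colour pair
differing along a null-space direction of (M − I)·alpha maps to the same
simulated colour, so the generated detail is guaranteed to be invisible to
the modelled observer.  For the red–green matrix that direction is
[1, −1, 0]; for the blue–yellow matrix it is [1, 1, −1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CONFUSION_AXES",
    "FixtureSpec",
    "GenerationError",
    "confusable_palette",
    "generate",
    "suite_specs",
    "fixture_suite",
]

KINDS = ("ishihara_plate", "chroma_edge", "chroma_ramp", "texture_field")

#: Unit null-space direction of each dichromat matrix: M v = 0.
CONFUSION_AXES = {
    "rg": np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0),
    "by": np.array([1.0, 1.0, -1.0]) / np.sqrt(3.0),
}


class GenerationError(RuntimeError):
    """Fixture generation failed (e.g. dot packing in too small a canvas)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic image.

    Same spec → bit-identical image.  ``palette`` is a pair of RGB triples
    (colour A, colour B) driving the dominant contrast.
    """

    kind: str
    size: tuple[int, int] = (128, 128)
    palette: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.7, 0.3, 0.5),
        (0.3, 0.7, 0.5),
    )
    seed: int = 0
    contrast: str = "rg"  # which observer class the palette is confusable for

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        pal = np.asarray(self.palette, dtype=np.float64)
        if pal.shape != (2, 3) or pal.min() < 0 or pal.max() > 1:
            raise ValueError("palette must be two RGB triples in [0, 1]")
        if self.contrast not in ("rg", "by"):
            raise ValueError(f"unknown contrast class {self.contrast!r}")


def confusable_palette(
    kind: str, base: np.ndarray, amplitude: float
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Colour pair ``base ± amplitude·axis`` invisible to a ``kind`` dichromat."""
    axis = CONFUSION_AXES[kind]
    a = np.asarray(base, dtype=np.float64) + amplitude * axis
    b = np.asarray(base, dtype=np.float64) - amplitude * axis
    if a.min() < 0 or a.max() > 1 or b.min() < 0 or b.max() > 1:
        raise ValueError("palette leaves the gamut; reduce amplitude or move base")
    return tuple(a), tuple(b)


def _digit_mask(height: int, width: int, digit: int) -> np.ndarray:
    """Boolean mask of a seven-segment numeral centred in the canvas."""
    segments = {
        0: "abcdef", 1: "bc", 2: "abged", 3: "abgcd", 4: "fgbc",
        5: "afgcd", 6: "afgecd", 7: "abc", 8: "abcdefg", 9: "abcdfg",
    }[digit % 10]
    t = 0.30  # segment thickness in digit-box units
    boxes = {  # (x0, x1, y0, y1) in unit digit-box coordinates, y down
        "a": (0.0, 1.0, 0.0, t),
        "b": (1.0 - t, 1.0, 0.0, 0.5),
        "c": (1.0 - t, 1.0, 0.5, 1.0),
        "d": (0.0, 1.0, 1.0 - t, 1.0),
        "e": (0.0, t, 0.5, 1.0),
        "f": (0.0, t, 0.0, 0.5),
        "g": (0.0, 1.0, 0.5 - t / 2, 0.5 + t / 2),
    }
    # digit box occupies the central 60% × 80% of the canvas
    box_w, box_h = 0.60 * width, 0.80 * height
    x_off, y_off = (width - box_w) / 2, (height - box_h) / 2
    yy, xx = np.mgrid[0:height, 0:width]
    u = (xx - x_off) / box_w
    v = (yy - y_off) / box_h
    mask = np.zeros((height, width), dtype=bool)
    for seg in segments:
        x0, x1, y0, y1 = boxes[seg]
        mask |= (u >= x0) & (u <= x1) & (v >= y0) & (v <= y1)
    return mask


def _ishihara_plate(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Dot plate: confusable palette dots on a mid-tone canvas.

    The canvas is a gently shaded dark neutral, so the saturated detail is
    localised in the dots — the structure (vivid regions with sharp
    boundaries against a smooth near-neutral surround, as with saturated
    objects over shadowed backgrounds) that colourful photographs exhibit.  Dots carry per-dot lightness jitter and a little
    saturation jitter along the confusion axis, i.e. fine detail that a
    dichromat cannot see.
    """
    h, w = spec.size
    pal_a, pal_b = (np.asarray(c) for c in spec.palette)
    axis = CONFUSION_AXES[spec.contrast]
    other_axis = CONFUSION_AXES["by" if spec.contrast == "rg" else "rg"]
    # secondary palette along the other confusion axis: colourful plates,
    # like photographs, carry both contrast classes
    centre = 0.5 * (pal_a + pal_b)
    sec_amp = 0.5 * float(np.linalg.norm(pal_a - pal_b))
    sec_a = np.clip(centre + sec_amp * other_axis, 0.02, 0.98)
    sec_b = np.clip(centre - sec_amp * other_axis, 0.02, 0.98)
    shade = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 6)
    span = np.abs(shade).max()
    if span > 0:
        shade = shade / span
    img = np.empty((h, w, 3))
    img[:] = 0.10 + 0.05 * shade[:, :, None]
    mask = _digit_mask(h, w, int(rng.integers(0, 10)))
    # large dots: saturated features must be big relative to the solver's
    # diffusion length, as in photographic content (and real plates)
    r_min = max(3, min(h, w) // 12)
    r_max = max(r_min + 1, min(h, w) // 6)
    centres: list[tuple[float, float, float]] = []
    attempts, max_attempts = 0, 6000
    yy, xx = np.mgrid[0:h, 0:w]
    while attempts < max_attempts:
        attempts += 1
        r = float(rng.uniform(r_min, r_max))
        cy = float(rng.uniform(r, h - r))
        cx = float(rng.uniform(r, w - r))
        if any((cy - y) ** 2 + (cx - x) ** 2 < (r + pr - 1.0) ** 2 for y, x, pr in centres):
            continue
        centres.append((cy, cx, r))
        rho2 = (yy - cy) ** 2 + (xx - cx) ** 2
        dot = rho2 <= r**2
        # assign by area overlap: dots are wider than the numeral strokes
        if mask[dot].mean() > 0.5:
            colour = pal_a
        else:
            # background dots: dominant pair with secondary-pair dots mixed in
            u = rng.random()
            if u < 0.7:
                colour = pal_b
            elif u < 0.85:
                colour = sec_a
            else:
                colour = sec_b
        lightness = float(rng.uniform(-0.015, 0.015))
        saturation = float(rng.uniform(-0.04, 0.04))
        # colourful content always carries some variation along the other
        # confusion axis as well
        cross = float(rng.uniform(-0.02, 0.02))
        colour = np.clip(
            colour + lightness + saturation * axis + cross * other_axis, 0.02, 0.98
        )
        # radial shading inside the dot: saturated regions in photographs
        # are shaded, never flat
        shading = 0.06 * (1.0 - rho2[dot] / r**2) - 0.03
        img[dot] = np.clip(colour + shading[:, None], 0.02, 0.98)
    if len(centres) < 6:
        raise GenerationError(
            f"packed only {len(centres)} dots on a {h}x{w} canvas; use a larger size"
        )
    return img


def generate(spec: FixtureSpec) -> np.ndarray:
    """Render a fixture spec into an H×W×3 image in [0, 1]; deterministic."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    pal_a, pal_b = (np.asarray(c, dtype=np.float64) for c in spec.palette)
    if spec.kind == "chroma_edge":
        img = np.empty((h, w, 3))
        img[:, : w // 2] = pal_a
        img[:, w // 2 :] = pal_b
        return img
    if spec.kind == "chroma_ramp":
        t = np.linspace(0.0, 1.0, w)[None, :, None]
        return np.broadcast_to((1 - t) * pal_a + t * pal_b, (h, w, 3)).copy()
    if spec.kind == "texture_field":
        # two scales of smooth noise: coarse patches with fine grain on top
        coarse = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 10)
        fine = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
        noise = coarse / max(np.abs(coarse).max(), 1e-12) + 0.35 * fine / max(
            np.abs(fine).max(), 1e-12
        )
        span = noise.max() - noise.min()
        t = (noise - noise.min()) / span if span > 0 else np.full((h, w), 0.5)
        # steepened mapping: saturated content is bimodal, with patches of
        # either palette colour separated by fairly sharp transitions
        t = 1.0 / (1.0 + np.exp(-6.0 * (t - 0.5)))
        img = (1 - t[:, :, None]) * pal_a + t[:, :, None] * pal_b
        # secondary chromatic variation along the other confusion axis, at
        # strength comparable to the dominant contrast
        other = CONFUSION_AXES["by" if spec.contrast == "rg" else "rg"]
        sec_amp = 0.5 * 0.5 * float(np.linalg.norm(pal_a - pal_b))
        ripple = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 12)
        ripple += 0.35 * gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
        ripple /= max(np.abs(ripple).max(), 1e-12)
        return np.clip(img + sec_amp * ripple[:, :, None] * other, 0.0, 1.0)
    return _ishihara_plate(spec, rng)


def suite_specs(n: int, seed: int, size: tuple[int, int] = (128, 128)) -> list[FixtureSpec]:
    """Deterministic suite recipes: kinds cycled, RG/BY palettes alternated."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        # offset by the row of the kind cycle so every kind appears in
        # both contrast classes
        cvd_kind = "rg" if (i + i // 4) % 2 == 0 else "by"
        # vivid complementary palettes straddling the neutral axis, as in
        # saturated photographic content (flowers against foliage)
        amplitude = float(rng.uniform(0.30, 0.38))
        # darkest base still leaving the pair inside the gamut
        lo = amplitude / np.sqrt(2.0) + 0.02
        base = rng.uniform(lo, 0.38, size=3)
        palette = confusable_palette(cvd_kind, base, amplitude)
        child_seed = int(rng.integers(0, 2**31))
        specs.append(
            FixtureSpec(
                kind=KINDS[i % 4],
                size=size,
                palette=palette,
                seed=child_seed,
                contrast=cvd_kind,
            )
        )
    return specs


def fixture_suite(
    n: int, seed: int, size: tuple[int, int] = (128, 128)
) -> list[np.ndarray]:
    """Generate the n-image synthetic evaluation suite for a seed."""
    return [generate(spec) for spec in suite_specs(n, seed, size)]
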