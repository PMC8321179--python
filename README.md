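# daltonise

Halo-free gradient-domain colour image daltonisation.

About one in twelve men has a colour vision deficiency (CVD): detail that
differs only along their confusion axis — typically red versus green — is
invisible to them.  *Daltonisation* recolours an image so that this lost
detail becomes visible, at the cost of altered colours.  This package
implements an individualised gradient-domain daltonisation method: any
image → image CVD simulation can drive it, so the recolouring adapts to
the modelled observer (deficiency class and severity), and a local linear
anisotropic diffusion reintegration removes the halo artefacts that plague
isotropic gradient-domain methods.

## Method in brief

For an image `u0` and observer simulation `s(·)` (here `s(u) = αMu +
(1−α)u` with the dichromat matrix `M` of the red–green or blue–yellow
class and severity `α ∈ [0,1]`):

1. lost information: `d0 = u0 − s(u0)`; its principal direction `p1`
   (uncentred PCA) is orthogonalised against the grey axis to give the
   basis `(el, ed, ec)` — lightness, lost-difference, and maximally
   visible chroma directions;
2. simple daltonisation: `us = clip(u0 + (u0·ed) ec)` — the closed-form
   estimate and initial value;
3. modified gradient tensor: `G = ∇u0 + (∇u0·ed) ec`;
4. reintegration by explicit projected gradient descent:
   `∂u/∂t = ∇·[D(∇u − G)]`, where `D` is the identity (isotropic
   baseline) or a per-pixel diffusion tensor with eigenvalues
   `d(λ) = 1/(1 + κλ²)` on the eigenvectors of the structure tensor of
   `u0`, computed once and frozen (local linear anisotropic diffusion).

`D` throttles diffusion across strong edges of the original image — that
is what suppresses halos.  Evaluation uses the gamut pixel fraction
(GPF: fraction of pixels with a channel at 0 or 1) and PSNR against the
original, compared per image with the Wilcoxon signed-rank test.

## Worked example

```python
import numpy as np
from daltonise import (FixtureSpec, SolverConfig, daltonise, generate,
                       gamut_pixel_fraction, make_observer, psnr)

img = generate(FixtureSpec(kind="ishihara_plate", size=(128, 128),
                           palette=((0.55, 0.06, 0.27), (0.06, 0.55, 0.27)),
                           seed=7, contrast="rg"))
observer = make_observer("rg", 1.0)          # red-green dichromat
for method in ("simple", "isotropic", "anisotropic"):
    out, diag = daltonise(img, observer, method=method, cfg=SolverConfig())
    print(f"{method:12s} iterations={diag.iterations:4d} "
          f"gpf={gamut_pixel_fraction(out):.3f} psnr={psnr(out, img):5.2f} dB")
```

prints

```
simple       iterations=   0 gpf=0.353 psnr=20.18 dB
isotropic    iterations=1000 gpf=0.050 psnr=18.39 dB
anisotropic  iterations=1000 gpf=0.048 psnr=20.56 dB
```

The simple method leaves 35% of pixels clipped to the gamut boundary
(texture destroyed in the saturated dots).  Both diffusion methods restore
that detail (GPF ≈ 5%), but the isotropic baseline leaks across the strong
dot edges, drifting more than 2 dB further from the original image; the
anisotropic method blocks that leakage.

The same pipeline is available from the shell:

```sh
daltonise fixtures --n 14 --seed 0 --outdir fixtures/
daltonise daltonise --method anisotropic --cvd rg --alpha 1.0 in.png out.png
daltonise simulate --cvd rg --alpha 1.0 out.png out_rg.png
daltonise metrics gpf out.png
daltonise evaluate --n 14 --seed 0 --outdir results/
```

`evaluate` runs every method against the four standard observers (RG/BY ×
α ∈ {1.0, 0.8}) over the synthetic suite and writes tidy per-run and
summary CSVs, including the isotropic-vs-anisotropic Wilcoxon p-values.

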