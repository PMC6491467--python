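# psfdecode

**Color and axial position from unmodified single-molecule PSF images.**

In single-molecule localization microscopy (SMLM/STORM), the diffraction
image (point spread function, PSF) of each fluorophore is usually treated as
a blob to be centered in 2D. Yet even with no PSF engineering, its detailed
shape already encodes two more parameters: the **emission wavelength** (a
longer-wavelength dye produces a proportionally wider PSF in all three
dimensions) and the **axial position** z (defocus reshapes the PSF, and
index-mismatch-induced spherical aberration makes the +z and −z shapes
distinguishable). `psfdecode` extracts both directly from raw 13 × 13 pixel
molecule images, with two complementary arms:

- **Parametric arm** — a tricubic-spline model S(x, y, z) of a reference PSF
  z-stack is fitted to each image by Poisson maximum likelihood,

  &nbsp;&nbsp;&nbsp;&nbsp;L(θ) = Σₖ [μₖ(θ) − nₖ log μₖ(θ)],&nbsp;&nbsp;
  μₖ(θ) = N·S(xₖ−x, yₖ−y, z) + b,

  with a dual z-initialization (+300 nm / −300 nm, keeping the lower
  likelihood error) to escape the near-symmetric local minimum; color is the
  spline model (one per dye) with the overall minimum likelihood error. The
  Fisher information Iᵢⱼ = Σₖ (∂μₖ/∂θᵢ)(∂μₖ/∂θⱼ)/μₖ gives the Cramér–Rao
  lower bound (CRLB) used as the precision reference everywhere.

- **Learning arm** — fully-connected networks (four ReLU hidden layers) on
  the zero-centered, unit-norm patch: a Softmax classifier returns the
  posterior P(dye | image) so each call carries a confidence
  Δ = P(dye₁|x) − P(dye₂|x); molecules with |Δ| < δ are rejected rather than
  guessed, trading retention for accuracy. Per-dye scalar-head regressors
  return z (and optionally the subpixel x/y offset).

Ground truth comes from a built-in **Gibson–Lanni simulator**: the
stratified-medium scalar diffraction integral (NA 1.45, oil n=1.51 into
water n=1.33, emitter 1 µm deep) sampled at 5 nm, integrated onto a 100 nm
pixel grid, photon-normalized over a 24 × 24 ROI and Poisson-sampled.

Intended users: microscopists and method developers who want multicolor 3D
SMLM from a single unmodified optical path, or a self-contained testbed for
PSF-based estimators.

## Worked example

```python
import numpy as np
from psfdecode import (GridConfig, OpticalConfig, psf_sim, spline_model,
                       mle_fitter)

grid = GridConfig()                       # ±600 nm / 20 nm, 5 nm → 100 nm pixels
optics = [OpticalConfig(emission_wavelength_nm=wl) for wl in (600, 700)]
stacks = [psf_sim.generate_psf_stack(o, grid) for o in optics]
models = [spline_model.build_spline_model(
              psf_sim.roi_normalized(psf_sim.downsample_to_detector(s, grid), grid))
          for s in stacks]

# simulate one 700 nm molecule at z = +200 nm, 5000 photons, 10 bg/pixel
truth = psf_sim.EmitterTruth(z_nm=200.0, photons=5000.0, background=10.0)
img, _ = psf_sim.render_molecule_image(stacks[1], truth, grid, rng_seed=7)

call = mle_fitter.classify_color_mle(img[6:19, 6:19], models)
fit = call.results[call.color]
bound = spline_model.crlb(models[1], spline_model.FitParameters(z_nm=200.0))
print(f"color index: {call.color}  (0 = 600 nm dye, 1 = 700 nm dye)")
print(f"z estimate : {fit.theta_hat.z_nm:.1f} nm  (truth 200.0)")
print(f"photons    : {fit.theta_hat.photons:.0f}")
print(f"CRLB sigma_z at this setting: {bound.z_nm:.1f} nm")
```

Output:

```
color index: 1  (0 = 600 nm dye, 1 = 700 nm dye)
z estimate : 175.9 nm  (truth 200.0)
photons    : 5032
CRLB sigma_z at this setting: 15.6 nm
```

The molecule is called as the 700 nm dye, its axial position is recovered
within about 1.5 CRLB standard deviations (σ_z ≈ 16 nm at this brightness
and defocus), and the fitted photon count matches the simulated brightness
to within shot noise. The same images drive the learning arm — see
`psfdecode.pipeline.run_full_benchmark`, or from a shell:

```bash
psfdecode pipeline benchmark --seed 1 --out scratch/benchmark
```

which simulates both dyes, builds spline models, trains the classifier and
both axial regressors, runs MLE and network arms, and writes `report.json`,
`localizations.csv` and diagnostic plots.

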