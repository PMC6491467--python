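# Methods

This note documents the models, conventions and numerical choices behind
`psfdecode`, in the spirit of a package's model documentation: what is
computed, under which assumptions, and where the genuinely open design
choices were made.

## PSF model (`psf_sim`)

The expected image of a point emitter is the stratified-medium scalar
diffraction (Gibson–Lanni) integral over the normalized pupil radius ρ:

    U(r; z) = ∫₀¹ exp(i k W(ρ)) J₀(k NA ρ r) ρ dρ,     k = 2π/λ
    W(ρ)    = z √(n_i² − NA²ρ²) + p [ √(n_s² − NA²ρ²) − √(n_i² − NA²ρ²) ]

with intensity |U|². Here `n_i` is the immersion index, `n_s` the sample
index, and `p` the emitter's depth below the coverslip. The first term is
ordinary defocus; the second is the depth-proportional spherical aberration
caused by the index mismatch, which is what makes PSF(+z) ≠ PSF(−z) and
therefore makes the axial sign recoverable from a single unmodified image.
For NA ρ > n_s the sample square root is continued into the complex plane
(positive imaginary branch), so supercritical pupil components decay
evanescently with depth instead of propagating.

Defaults mirror a high-NA oil-immersion STORM setup: NA 1.45, n_i 1.51,
n_s 1.33, working distance 130 µm, depth 1 µm, λ ∈ {600, 700} nm.

**Quadrature.** Gauss–Legendre with node doubling (64 → 4096) until two
successive intensity evaluations agree to 1e-6 of the profile peak. The
integrand has a branch point at the critical angle ρ_c = n_s/NA; the
interval is split into panels [0, ρ_c] and [ρ_c, 1] so each panel is
analytic — without the split, convergence is only algebraic and the
tolerance is unreachable at any practical node count. In the matched-index,
in-focus limit the integral reduces to the Airy pattern
(2 J₁(x)/x)², which the tests use as the closed-form oracle (agreement to
~1e-15; first zero at 0.61 λ/NA).

**Axial origin.** At 1 µm depth the spherical aberration displaces the
plane of best focus by roughly −380 nm from the nominal (aberration-free)
focal plane. Since an experimenter focuses on the sharpest image, stacks
are generated with z measured from the on-axis intensity maximum
(`best_focus_offset_nm`, located by coarse scan plus bounded refinement).
z > 0 means the emitter is farther from the coverslip than the focal
plane; this sign convention is applied uniformly in simulation, training
labels and inference output.

**Sampling and rendering.** The radially symmetric profile is evaluated on
a dense radius table and interpolated onto a 5 nm grid covering a 25 px
(2.5 µm) field; 61 slices span ±600 nm in 20 nm steps; the stack is scaled
to unit peak. Detector images are exact block sums over 20 × 20 fine
samples per 100 nm pixel (flux is conserved to rounding error, which the
tests check at 1e-10). A molecule image is rendered by linear z
interpolation between fine slices, a lateral shift applied on the fine
grid *before* binning (so training data contain true subpixel pixelation
phase, quantized at 5 nm), scaling so the central 24 × 24 ROI sums to the
photon count, adding the uniform background, and drawing one Poisson
sample per pixel. Each image uses an independent counter-keyed RNG
substream `(seed, image_index)`, so datasets are reproducible and
order-independent. EM-CCD excess noise, gain/offset, and sCMOS pixel maps
are deliberately out of scope: the noise model is pure Poisson.

Study conditions baked into the dataset generator defaults: two colors
600/700 nm, background 10 photons/pixel, photon counts drawn from the
4500–5500 band for training (so the network sees one consistent noise
level) and fixed at 5000 or 2000 for evaluation, z uniform over ±400 nm
for classification and ±600 nm for regression, random subpixel x/y offsets
(±half pixel) on by default.

## Spline model and CRLB (`spline_model`)

A detector-resolution reference stack is interpolated by a tensor-product
natural cubic spline: three separable 1D passes (x, y, z) yield 64
polynomial coefficients per cell, giving a C² model that interpolates the
stack exactly at every knot and reproduces constant and linear fields
exactly. The outermost knot shell is excluded from the fit domain to avoid
extrapolation artifacts. Evaluation returns values and analytic first
derivatives (verified against central differences at 1e-5).

**Amplitude convention.** The reference stack is normalized per slice so
that its 24 × 24 ROI sums to 1 (`roi_normalized`). This matches the
renderer's photon convention — every rendered image's ROI sum equals its
photon count at every z — so the fitted `photons` parameter is in actual
detected counts. (A unit-peak convention would decouple the photon
parameter from detected counts; the chosen convention is recorded in the
model metadata.)

Under the Poisson model, μ_k(θ) = N·S(x_k−x, y_k−y, z) + b with
θ = (x, y, z, N, b), the Fisher information is
I_ij = Σ_k (∂μ_k/∂θ_i)(∂μ_k/∂θ_j)/μ_k and the CRLB per parameter is the
square root of the corresponding diagonal entry of I⁻¹. Representative
values at 5000 photons / 10 bg (700 nm dye): σ_x ≈ 1.8–3 nm and
σ_z ≈ 7–25 nm across ±400 nm, with the z bound largest near focus, where
the nearly symmetric PSF encodes z weakly.

## MLE fitting (`mle_fitter`)

The likelihood error is the negative Poisson log-likelihood with the
θ-independent log(n!) term dropped; spline values are floored at 1e-6
before entering the log, so near-zero tails cannot produce invalid rates.
Minimization is damped Fisher-scoring Newton (Levenberg diagonal loading,
rejected steps re-damped, so accepted iterations decrease L
monotonically), with at most 100 iterations and convergence when every
parameter update falls below (0.01 nm positions, 0.1 photons, 0.001
background). Parameters are clamped to the spline domain each step.
Initialization is deterministic: x/y from the intensity-weighted centroid,
background from the 20th-percentile pixel, photons from the
background-subtracted sum.

Because the z likelihood of a near-symmetric PSF is bimodal, every fit is
run twice from z = +300 nm and z = −300 nm and the branch with the lower
likelihood error is kept (ties break toward the first-listed branch).
Color classification runs this dual fit against each dye's model — four
MLE rounds for two colors — and picks the minimum-error model (ties break
toward the lower color index). Monte-Carlo efficiency: across 500 Poisson
replicates per z at 5000 photons / 10 bg, std(ẑ)/CRLB_z measured 0.93–1.05
at z ∈ {±100, ±300} nm, i.e. the fitter is essentially efficient; the
lower edge of the acceptance band allows 3σ of sampling noise in the
sample standard deviation (3.2% at n = 500).

## Preprocessing (`preprocess`)

Frames are screened by 5 × 5 local maxima above a threshold (default:
background median + 5√background, with the background estimated as the
frame median), refined by isotropic 2D Gaussian least squares
(amplitude, center, single σ, offset), photons estimated as 2πAσ².
Molecules are cropped to 13 × 13 at the nearest-pixel center — no subpixel
re-interpolation, so the networks learn pixelation jitter. Screens applied
to the full candidate list (hence order-independent): both members of any
pair closer than 1 µm are removed; fitted widths 2σ > 400 nm are removed;
edge-clipped crops are removed; an optional photon band partitions
training (4500–5500) from brighter validation molecules. "Zero-centered"
is implemented as per-patch mean subtraction followed by unit Euclidean
norm — the patch-local reading that pairs naturally with norm scaling.
Pixel indices are 0-based with the origin at the top-left pixel center.
The detector here is a declared stand-in for a full SMLM localizer,
validated on simulation; drift correction and frame linking are out of
scope.

## Networks (`networks`)

One architecture for both tasks: four fully-connected ReLU hidden layers
(study scale 4096-4096-2048-1024 on the 169-dimensional normalized patch),
Xavier-uniform initialization, Adam, learning rate × 0.2 every 1000
iterations. The classifier ends in Softmax, is trained with cross-entropy
on class-balanced (stratified) batches of 64 at initial rate 1e-4, and is
regularized only by dropout 0.5 before the final layer. The regressors end
in a scalar, are trained with mean squared error plus an L2 weight penalty
(0.01) on batches of 32 at initial rate 1e-3, without dropout; one
regressor per dye. Training stops at the epoch budget or after a
3-to-5-epoch validation plateau, keeping the best-validation weights.
Dropout is disabled at inference, so outputs are deterministic, and all
training is plain numpy — bit-reproducible given the seed.

The binary confidence is Δ = P(class 0) − P(class 1) (generalized to top
minus runner-up for M > 2, which reduces to the binary form at M = 2); a
molecule is accepted iff |Δ| ≥ δ, with δ ∈ {0, 0.4, 0.8} as the standard
operating points.

**Desk-scale sizes.** The test suite and acceptance script keep the
four-layer architecture but use narrower layers (256-256-128-64 classifier,
512-256-128-64 regressor) and smaller sets (3000/class classifier,
6000 axial) — chosen as the smallest configuration that cleanly clears the
scientific targets (classifier ≥ 95% at 5000 photons; regressor slope
0.9–1.1 and std within 2× CRLB at ±200 nm). `BenchmarkConfig` defaults
remain the study-scale values.

## Pipeline (`pipeline`)

Inference follows: photometry threshold (exposed, 3000 photons by default)
→ color call at δ → routing of accepted molecules to the regressor of the
called dye → merged records (frame, x, y, z, color, photons, confidence).
Rejected and filtered molecules remain in the output as explicit records,
so accepted + rejected + filtered always equals the input count.
Evaluation summaries stratify accuracy-among-accepted and rejection rate
by threshold, photon bin and true z (empty strata report NaN, not zero);
axial evaluation reports per-true-z bias and std with an optional CRLB
overlay. `run_full_benchmark` reproduces the whole simulated study from
one seed and writes a JSON report, a localization CSV and plots; two runs
with the same seed produce identical reports.

## What the simulation does and does not show

The simulator reproduces the physics that carries the signal — wavelength
scaling of the PSF, defocus broadening, depth-induced axial asymmetry,
Poisson noise at realistic photon/background levels, pixelation — so
passing tests demonstrate that the estimators extract color and z from
exactly those cues at the stated brightnesses. It does not emulate
EM-CCD excess noise, spatially varying or dipole-orientation PSFs, sample
drift, or chromatic offsets between dyes' optical paths; measured
accuracies on real STORM data will be correspondingly lower, and the
training-data pathway for user-supplied experimental stacks exists for
that reason. Lateral (x/y) network estimation is implemented and tested at
the same machinery level but is secondary to the color + z workflow.

## Known limitations

- Single-emitter fitting only; overlapping molecules are rejected by the
  1 µm rule rather than deconvolved.
- The MLE's dual initialization can still cross basins very near focus,
  where the two branches tie; the tie-break is deterministic but the sign
  of very small z is genuinely poorly determined (large CRLB_z at z ≈ 0).
- The renderer quantizes lateral shifts at the 5 nm fine grid; sub-5 nm
  lateral truth is not representable in training data.
- Spline models inherit any normalization mismatch between reference stack
  and data; models built from noisy experimental stacks should average
  aligned bead images first (`build_spline_model` accepts any stack).
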