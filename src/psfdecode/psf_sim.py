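"""Scalar-diffraction PSF simulation for an index-mismatched sample.

The point-spread function of a high-NA objective imaging an emitter at depth
``p`` below the coverslip, through an immersion medium of index ``n_i`` into a
sample medium of index ``n_s``, is modeled with the stratified-medium
(Gibson–Lanni) optical-path-difference integral

    U(r; z) = \\int_0^1 exp(i k W(rho)) J_0(k NA rho r) rho d rho

    W(rho)  = z sqrt(n_i^2 - NA^2 rho^2)
              + p [ sqrt(n_s^2 - NA^2 rho^2) - sqrt(n_i^2 - NA^2 rho^2) ]

with ``k = 2 pi / lambda`` and intensity ``|U|^2``.  ``z`` is the defocus of
the emitter relative to the focal plane; ``z > 0`` means the emitter is
farther from the coverslip than the focal plane.  For ``NA rho > n_s`` the
sample-medium square root is taken complex with positive imaginary part, so
supercritical pupil components decay evanescently with depth.  When the two
indices match and ``z = 0`` the integral reduces to the Airy pattern, which
serves as the closed-form check of the quadrature.

The continuous model is sampled on a fine lateral grid (default 5 nm), then
integrated over detector pixels (default 100 nm) by exact block summation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import j0, j1

from .config import ConfigurationError, GridConfig, OpticalConfig

__all__ = [
    "IntegrationError",
    "PSFStack",
    "EmitterTruth",
    "radial_intensity_profile",
    "airy_intensity",
    "gibson_lanni_slice",
    "generate_psf_stack",
    "downsample_to_detector",
    "expected_molecule_image",
    "render_molecule_image",
    "generate_benchmark_dataset",
    "save_dataset",
]


class IntegrationError(RuntimeError):
    """Pupil quadrature failed to converge to the requested tolerance."""


@dataclass
class PSFStack:
    """A gridded expected-intensity model of a PSF over (z, y, x).

    ``values`` is indexed ``(z, y, x)``; lateral sample coordinates are
    ``(i + 0.5 - n/2) * pixel_size_nm`` so the grid is symmetric about the
    optical axis.  ``normalization`` records the amplitude convention.
    """

    values: np.ndarray
    z_positions_nm: np.ndarray
    pixel_size_nm: float
    wavelength_nm: float
    normalization: str = "peak=1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.z_positions_nm = np.asarray(self.z_positions_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("PSFStack values must be 3D (z, y, x)")
        if len(self.z_positions_nm) != self.values.shape[0]:
            raise ValueError("z_positions_nm length must match slice count")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("PSFStack values must be finite and nonnegative")
        dz = np.diff(self.z_positions_nm)
        if len(dz) and (np.any(dz <= 0) or np.ptp(dz) > 1e-6):
            raise ValueError("z_positions_nm must be strictly increasing and uniform")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def z_step_nm(self) -> float:
        if self.n_slices < 2:
            return 0.0
        return float(self.z_positions_nm[1] - self.z_positions_nm[0])

    def slice_at(self, z_nm: float) -> np.ndarray:
        """Linear interpolation of the stack between adjacent z slices."""
        zp = self.z_positions_nm
        if z_nm < zp[0] or z_nm > zp[-1]:
            raise ValueError(
                f"z={z_nm} nm outside stack range [{zp[0]}, {zp[-1]}] nm"
            )
        idx = np.searchsorted(zp, z_nm)
        if idx == 0:
            return self.values[0]
        lo, hi = idx - 1, min(idx, self.n_slices - 1)
        if lo == hi:
            return self.values[lo]
        w = (z_nm - zp[lo]) / (zp[hi] - zp[lo])
        return (1.0 - w) * self.values[lo] + w * self.values[hi]


@dataclass(frozen=True)
class EmitterTruth:
    """Ground-truth record attached to every simulated molecule image."""

    x_nm: float = 0.0
    y_nm: float = 0.0
    z_nm: float = 0.0
    photons: float = 5000.0
    background: float = 10.0
    color_label: int = 0

    def __post_init__(self) -> None:
        if self.photons < 0 or self.background < 0:
            raise ValueError("photons and background must be nonnegative")


# ---------------------------------------------------------------------------
# pupil quadrature
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    # Gauss-Legendre nodes/weights mapped from [-1, 1] to [0, 1]
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _opd(optics: OpticalConfig, rho: np.ndarray, z_nm: float) -> np.ndarray:
    """Optical path difference W(rho) in nm (complex above the critical angle)."""
    na2rho2 = (optics.numerical_aperture * rho) ** 2
    ni_term = np.sqrt(optics.immersion_index**2 - na2rho2)  # real: NA <= n_i
    ns_arg = optics.sample_index**2 - na2rho2
    ns_term = np.sqrt(ns_arg.astype(complex))  # +i branch for evanescent part
    depth_nm = optics.particle_depth_um * 1000.0
    return z_nm * ni_term + depth_nm * (ns_term - ni_term)


def _pupil_breakpoints(optics: OpticalConfig) -> tuple[float, ...]:
    """Pupil-radius panels; split at the critical angle where sqrt(n_s^2 -
    NA^2 rho^2) has a branch point, so each panel is analytic."""
    rho_c = optics.sample_index / optics.numerical_aperture
    if 0.0 < rho_c < 1.0:
        return (0.0, rho_c, 1.0)
    return (0.0, 1.0)


def _field_with_nodes(
    optics: OpticalConfig, z_nm: float, radii_nm: np.ndarray, n_nodes: int
) -> np.ndarray:
    base_rho, base_w = _gl_nodes(n_nodes)
    k = 2.0 * np.pi / optics.emission_wavelength_nm
    out = np.zeros(len(radii_nm), dtype=complex)
    pts = _pupil_breakpoints(optics)
    for a, b in zip(pts[:-1], pts[1:]):
        rho = a + (b - a) * base_rho
        w = (b - a) * base_w
        phase = np.exp(1j * k * _opd(optics, rho, z_nm))
        bessel = j0(k * optics.numerical_aperture * np.outer(rho, radii_nm))
        out += (w * rho * phase) @ bessel
    return out


def radial_amplitude(
    optics: OpticalConfig,
    z_nm: float,
    radii_nm: np.ndarray,
    rtol: float = 1e-6,
    max_nodes: int = 4096,
) -> np.ndarray:
    """Complex field amplitude at the given radii, by adaptive G-L quadrature.

    Node count is doubled until successive intensity evaluations agree to
    ``rtol`` relative to the profile peak.
    """
    radii_nm = np.asarray(radii_nm, dtype=float)
    n = 64
    prev = _field_with_nodes(optics, z_nm, radii_nm, n)
    while n < max_nodes:
        n *= 2
        cur = _field_with_nodes(optics, z_nm, radii_nm, n)
        scale = np.max(np.abs(cur) ** 2)
        err = np.max(np.abs(np.abs(cur) ** 2 - np.abs(prev) ** 2))
        if err <= rtol * scale:
            return cur
        prev = cur
    raise IntegrationError(
        f"pupil quadrature did not converge at {max_nodes} nodes "
        f"(z={z_nm} nm, residual={err:.3e}, scale={scale:.3e})"
    )


def radial_intensity_profile(
    optics: OpticalConfig, z_nm: float, radii_nm: np.ndarray
) -> np.ndarray:
    """Unnormalized radial intensity |U(r; z)|^2."""
    return np.abs(radial_amplitude(optics, z_nm, radii_nm)) ** 2


def airy_intensity(optics: OpticalConfig, radii_nm: np.ndarray) -> np.ndarray:
    """Closed-form Airy intensity (2 J1(x)/x)^2, normalized to 1 on axis.

    This is the matched-index, in-focus limit of the diffraction integral;
    its first zero sits at ``0.61 lambda / NA``.
    """
    x = (
        2.0 * np.pi
        / optics.emission_wavelength_nm
        * optics.numerical_aperture
        * np.asarray(radii_nm, dtype=float)
    )
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (2.0 * j1(x[nz]) / x[nz]) ** 2
    return out


# ---------------------------------------------------------------------------
# gridded stacks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def best_focus_offset_nm(optics: OpticalConfig) -> float:
    """Defocus value that maximizes the on-axis intensity.

    With an index mismatch, spherical aberration displaces the plane of best
    focus from the nominal (aberration-free) focal plane.  An experimenter
    focuses on the sharpest image, so gridded stacks are produced with z
    measured from this plane.  Matched-index configurations need no offset.
    """
    if optics.matched_index:
        return 0.0
    from scipy.optimize import minimize_scalar

    r0 = np.zeros(1)

    def neg_axial_intensity(z: float) -> float:
        return -float(np.abs(_field_with_nodes(optics, z, r0, 256)[0]) ** 2)

    zs = np.linspace(-1500.0, 1500.0, 151)
    coarse = zs[int(np.argmin([neg_axial_intensity(z) for z in zs]))]
    res = minimize_scalar(
        neg_axial_intensity, bounds=(coarse - 40.0, coarse + 40.0), method="bounded"
    )
    return float(res.x)


def _fine_grid_coords(grid: GridConfig) -> np.ndarray:
    n_fine = grid.detector_size_px * grid.binning_factor
    return (np.arange(n_fine) + 0.5 - n_fine / 2) * grid.fine_resolution_nm


def gibson_lanni_slice(
    optics: OpticalConfig, z_nm: float, grid: GridConfig
) -> np.ndarray:
    """One fine-resolution intensity slice at defocus ``z_nm`` (unnormalized).

    The radial profile is computed by quadrature on a dense radius table and
    interpolated onto the square grid; the PSF model is radially symmetric so
    no accuracy is lost.
    """
    if abs(z_nm) > grid.z_range_nm:
        raise ValueError(f"|z|={abs(z_nm)} nm exceeds z_range {grid.z_range_nm} nm")
    coords = _fine_grid_coords(grid)
    r = np.hypot.outer(coords, coords)
    r_table = np.arange(
        0.0, r.max() + grid.fine_resolution_nm, 0.5 * grid.fine_resolution_nm
    )
    # z is measured from the plane of best focus (see best_focus_offset_nm)
    profile = radial_intensity_profile(
        optics, z_nm + best_focus_offset_nm(optics), r_table
    )
    return np.interp(r, r_table, profile)


def generate_psf_stack(optics: OpticalConfig, grid: GridConfig) -> PSFStack:
    """Fine-resolution PSF stack over the symmetric defocus range.

    ``2 * z_range / z_step + 1`` slices; intensities scaled so the brightest
    sample of the whole stack (the in-focus, on-axis region for a
    well-corrected configuration) equals 1.
    """
    n_steps = int(round(grid.z_range_nm / grid.z_step_nm))
    z_positions = np.arange(-n_steps, n_steps + 1) * grid.z_step_nm
    slices = np.stack([gibson_lanni_slice(optics, z, grid) for z in z_positions])
    slices /= slices.max()
    return PSFStack(
        values=slices,
        z_positions_nm=z_positions,
        pixel_size_nm=grid.fine_resolution_nm,
        wavelength_nm=optics.emission_wavelength_nm,
        normalization="peak=1",
    )


@lru_cache(maxsize=4)
def _cached_stack(optics: OpticalConfig, grid: GridConfig) -> PSFStack:
    return generate_psf_stack(optics, grid)


def generate_psf_stack_cached(optics: OpticalConfig, grid: GridConfig) -> PSFStack:
    """Memoized ``generate_psf_stack``; treat the returned stack as read-only."""
    return _cached_stack(optics, grid)


def downsample_to_detector(stack: PSFStack, grid: GridConfig) -> PSFStack:
    """Integrate the fine grid over detector pixels (exact block summation).

    Each output pixel is the sum of the ``b x b`` fine samples it covers,
    ``b = pixel_size / fine_resolution``; trailing samples that do not fill a
    whole pixel are truncated.
    """
    ratio = grid.pixel_size_nm / stack.pixel_size_nm
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError(
            f"pixel size {grid.pixel_size_nm} nm is not an integer multiple of "
            f"the stack resolution {stack.pixel_size_nm} nm"
        )
    b = int(round(ratio))
    nz, ny, nx = stack.values.shape
    my, mx = ny // b, nx // b
    v = stack.values[:, : my * b, : mx * b]
    binned = v.reshape(nz, my, b, mx, b).sum(axis=(2, 4))
    return PSFStack(
        values=binned,
        z_positions_nm=stack.z_positions_nm.copy(),
        pixel_size_nm=grid.pixel_size_nm,
        wavelength_nm=stack.wavelength_nm,
        normalization=stack.normalization + ";binned",
    )


# ---------------------------------------------------------------------------
# molecule-image rendering
# ---------------------------------------------------------------------------

def roi_normalized(stack: PSFStack, grid: GridConfig) -> PSFStack:
    """Rescale every slice so its central ROI window sums to 1.

    This matches the renderer's photon convention (the ROI sum of each
    rendered image equals the emitter's photon count at every z), so a spline
    model built from the normalized stack has a ``photons`` parameter in
    actual detected counts.
    """
    n = stack.values.shape[1]
    s = (n - grid.roi_size_px) // 2
    sums = stack.values[:, s : s + grid.roi_size_px, s : s + grid.roi_size_px].sum(
        axis=(1, 2)
    )
    if np.any(sums <= 0):
        raise ValueError("a slice has no flux inside the normalization ROI")
    return PSFStack(
        values=stack.values / sums[:, None, None],
        z_positions_nm=stack.z_positions_nm.copy(),
        pixel_size_nm=stack.pixel_size_nm,
        wavelength_nm=stack.wavelength_nm,
        normalization="roi_sum=1",
    )


def _shift_fine(field: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift with zero fill (no wraparound)."""
    out = np.zeros_like(field)
    ny, nx = field.shape
    ys = slice(max(dy, 0), min(ny, ny + dy))
    xs = slice(max(dx, 0), min(nx, nx + dx))
    yo = slice(max(-dy, 0), min(ny, ny - dy))
    xo = slice(max(-dx, 0), min(nx, nx - dx))
    out[ys, xs] = field[yo, xo]
    return out


def expected_molecule_image(
    stack: PSFStack, truth: EmitterTruth, grid: GridConfig
) -> np.ndarray:
    """Noiseless expected detector frame for one emitter.

    The fine-resolution slice at ``truth.z`` is shifted laterally (at fine
    granularity, before binning, to avoid pixelation bias), integrated over
    detector pixels, scaled so the sum over the central
    ``roi_size x roi_size`` window equals ``truth.photons``, then offset by
    the uniform background.
    """
    fine = stack.slice_at(truth.z_nm)
    dx = int(round(truth.x_nm / stack.pixel_size_nm))
    dy = int(round(truth.y_nm / stack.pixel_size_nm))
    if dx or dy:
        fine = _shift_fine(fine, dy, dx)
    detector = downsample_to_detector(
        PSFStack(fine[None], [truth.z_nm], stack.pixel_size_nm, stack.wavelength_nm),
        grid,
    ).values[0]
    n = detector.shape[0]
    s = (n - grid.roi_size_px) // 2
    roi_sum = detector[s : s + grid.roi_size_px, s : s + grid.roi_size_px].sum()
    if truth.photons > 0:
        if roi_sum <= 0:
            raise ValueError("PSF has no flux inside the normalization ROI")
        detector = detector * (truth.photons / roi_sum)
    else:
        detector = np.zeros_like(detector)
    return detector + truth.background


def render_molecule_image(
    stack: PSFStack,
    truth: EmitterTruth,
    grid: GridConfig,
    rng_seed,
) -> tuple[np.ndarray, EmitterTruth]:
    """One Poisson draw of the expected frame; same seed, same image."""
    expected = expected_molecule_image(stack, truth, grid)
    rng = np.random.default_rng(rng_seed)
    return rng.poisson(expected).astype(float), truth


# ---------------------------------------------------------------------------
# benchmark datasets
# ---------------------------------------------------------------------------

def _draw(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Resolve a distribution spec: scalar, (low, high) uniform, or callable."""
    if callable(spec):
        return np.asarray(spec(rng, n), dtype=float)
    if np.isscalar(spec):
        return np.full(n, float(spec))
    low, high = spec
    return rng.uniform(low, high, size=n)


def generate_benchmark_dataset(
    optics_per_color: Sequence[OpticalConfig],
    grid: GridConfig,
    n_per_color: int,
    photon_distribution=5000.0,
    background: float = 10.0,
    z_distribution=(-400.0, 400.0),
    rng_seed: int = 0,
    stacks: Sequence[PSFStack] | None = None,
    subpixel_offsets: bool = True,
    crop_to_patch: bool = True,
) -> list[tuple[np.ndarray, EmitterTruth]]:
    """Labeled two-(or more-)color dataset of noisy molecule images.

    Each image gets an independent Poisson substream keyed by
    ``(rng_seed, image_index)`` so generation order never changes the data.
    Pre-generated fine stacks may be passed to skip the diffraction integral.
    """
    if len(optics_per_color) == 0:
        raise ConfigurationError("at least one color (OpticalConfig) is required")
    if n_per_color < 1:
        raise ConfigurationError("n_per_color must be >= 1")
    if stacks is None:
        stacks = [generate_psf_stack(o, grid) for o in optics_per_color]
    half_px = grid.pixel_size_nm / 2.0
    dataset: list[tuple[np.ndarray, EmitterTruth]] = []
    index = 0
    for color, stack in enumerate(stacks):
        rng = np.random.default_rng([rng_seed, 7919, color])
        photons = _draw(photon_distribution, rng, n_per_color)
        zs = _draw(z_distribution, rng, n_per_color)
        if subpixel_offsets:
            xy = rng.uniform(-half_px, half_px, size=(n_per_color, 2))
        else:
            xy = np.zeros((n_per_color, 2))
        for i in range(n_per_color):
            truth = EmitterTruth(
                x_nm=float(xy[i, 0]),
                y_nm=float(xy[i, 1]),
                z_nm=float(zs[i]),
                photons=float(photons[i]),
                background=background,
                color_label=color,
            )
            img, _ = render_molecule_image(stack, truth, grid, [rng_seed, index])
            if crop_to_patch:
                n = img.shape[0]
                s = (n - grid.patch_size_px) // 2
                img = img[s : s + grid.patch_size_px, s : s + grid.patch_size_px]
            dataset.append((img, truth))
            index += 1
    return dataset


def save_dataset(
    dataset: Sequence[tuple[np.ndarray, EmitterTruth]],
    path: str | Path,
    config: dict | None = None,
) -> None:
    """Write images as multi-page TIFF (uint16) with a CSV truth sidecar."""
    import pandas as pd
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    images = np.stack([np.clip(img, 0, 65535) for img, _ in dataset])
    tifffile.imwrite(path, images.astype(np.uint16), photometric="minisblack")
    rows = [
        {
            "frame": i,
            "x_nm": t.x_nm,
            "y_nm": t.y_nm,
            "z_nm": t.z_nm,
            "photons": t.photons,
            "background": t.background,
            "color_label": t.color_label,
        }
        for i, (_, t) in enumerate(dataset)
    ]
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
    if config is not None:
        path.with_suffix(".json").write_text(json.dumps(config, indent=2))
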