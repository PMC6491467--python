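"""Tricubic-spline PSF models, Fisher information and Cramér–Rao bounds.

A reference z-stack (one detector-resolution image every ``z_step`` nm) is
interpolated by a tensor-product natural cubic spline, giving a C²,
analytically differentiable forward model ``S(x, y, z)``.  Under the Poisson
imaging model the expected count in pixel ``k`` is

    mu_k(theta) = photons * S(x_k - x, y_k - y, z) + background

and the Fisher information matrix is

    I_ij = sum_k (d mu_k / d theta_i)(d mu_k / d theta_j) / mu_k

whose inverse diagonal gives the Cramér–Rao lower bound on the variance of
any unbiased estimator of theta = (x, y, z, photons, background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .config import ConfigurationError
from .psf_sim import PSFStack

__all__ = [
    "SplinePSFModel",
    "FitParameters",
    "CRLBResult",
    "DomainError",
    "ModelValidityError",
    "DegeneracyError",
    "build_spline_model",
    "evaluate_psf",
    "fisher_information",
    "crlb",
]

PARAM_NAMES = ("x", "y", "z", "photons", "background")


class DomainError(ValueError):
    """Requested evaluation point lies outside the spline's valid domain."""


class ModelValidityError(ValueError):
    """The expected image is not a valid Poisson rate (mu <= 0 somewhere)."""


class DegeneracyError(np.linalg.LinAlgError):
    """Fisher information matrix is numerically singular."""


@dataclass(frozen=True)
class FitParameters:
    """Parameter vector theta of the Poisson imaging model (nm / counts)."""

    x_nm: float = 0.0
    y_nm: float = 0.0
    z_nm: float = 0.0
    photons: float = 5000.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photons must be positive")
        if self.background < 0:
            raise ValueError("background must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_nm, self.y_nm, self.z_nm, self.photons, self.background]
        )

    @staticmethod
    def from_array(a) -> "FitParameters":
        return FitParameters(*(float(v) for v in a))


@dataclass
class CRLBResult:
    """Per-parameter lower-bound standard deviations (same units as theta)."""

    x_nm: float
    y_nm: float
    z_nm: float
    photons: float
    background: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_nm, self.y_nm, self.z_nm, self.photons, self.background]
        )


class SplinePSFModel:
    """Piecewise-tricubic interpolant of a PSF stack.

    ``coefficients[iz, iy, ix, a, b, c]`` multiplies ``tz**a * ty**b * tx**c``
    inside cell ``(iz, iy, ix)``, with ``t`` the fractional position in knot
    units.  Knots coincide with stack samples; lateral knot spacing is the
    detector pixel, axial spacing the stack z step.  The outermost knot shell
    is excluded from the valid domain to avoid boundary extrapolation
    artifacts.  Spline amplitude follows the source stack's unit-peak
    convention (recorded in ``normalization``).
    """

    def __init__(
        self,
        coefficients: np.ndarray,
        knot_spacings_nm: tuple[float, float, float],
        origin_nm: tuple[float, float, float],
        wavelength_nm: float,
        source_stack_id: str = "",
        normalization: str = "peak=1",
    ) -> None:
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.ndim != 6 or coefficients.shape[3:] != (4, 4, 4):
            raise ValueError("coefficients must have shape (nz-1, ny-1, nx-1, 4, 4, 4)")
        self.coefficients = coefficients
        self.knot_spacings_nm = tuple(float(s) for s in knot_spacings_nm)
        self.origin_nm = tuple(float(o) for o in origin_nm)
        self.wavelength_nm = float(wavelength_nm)
        self.source_stack_id = source_stack_id
        self.normalization = normalization

    @property
    def n_knots(self) -> tuple[int, int, int]:
        nz, ny, nx = self.coefficients.shape[:3]
        return nz + 1, ny + 1, nx + 1

    # -- evaluation ---------------------------------------------------------

    def _check_domain(self, pts: np.ndarray) -> None:
        upper = np.array(self.n_knots, dtype=float) - 2.0
        if np.any(pts < 1.0 - 1e-9) or np.any(pts > upper + 1e-9):
            raise DomainError(
                "evaluation point outside the interior knot domain "
                f"[1, {upper}] (knot units)"
            )

    def evaluate(
        self, pts_knot: np.ndarray, check_domain: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Value and gradient at points given in knot units (z, y, x).

        Returns ``(values (P,), gradients (P, 3))`` with gradients ordered
        (d/dz, d/dy, d/dx) per knot unit.
        """
        pts = np.atleast_2d(np.asarray(pts_knot, dtype=float))
        if check_domain:
            self._check_domain(pts)
        ncells = np.array(self.coefficients.shape[:3])
        cell = np.clip(np.floor(pts).astype(int), 0, ncells - 1)
        t = pts - cell
        C = self.coefficients[cell[:, 0], cell[:, 1], cell[:, 2]]  # (P,4,4,4)
        powers = np.arange(4)
        pz = t[:, 0:1] ** powers
        py = t[:, 1:2] ** powers
        px = t[:, 2:3] ** powers
        dpz = np.zeros_like(pz)
        dpz[:, 1:] = powers[1:] * t[:, 0:1] ** (powers[1:] - 1)
        dpy = np.zeros_like(py)
        dpy[:, 1:] = powers[1:] * t[:, 1:2] ** (powers[1:] - 1)
        dpx = np.zeros_like(px)
        dpx[:, 1:] = powers[1:] * t[:, 2:3] ** (powers[1:] - 1)
        val = np.einsum("pabc,pa,pb,pc->p", C, pz, py, px)
        dz = np.einsum("pabc,pa,pb,pc->p", C, dpz, py, px)
        dy = np.einsum("pabc,pa,pb,pc->p", C, pz, dpy, px)
        dx = np.einsum("pabc,pa,pb,pc->p", C, pz, py, dpx)
        return val, np.stack([dz, dy, dx], axis=1)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Model bundle: one npz (coefficient blob) + JSON-style metadata."""
        np.savez_compressed(
            path,
            schema=np.array([1]),
            coefficients=self.coefficients,
            knot_spacings_nm=np.array(self.knot_spacings_nm),
            origin_nm=np.array(self.origin_nm),
            wavelength_nm=np.array([self.wavelength_nm]),
            source_stack_id=np.array([self.source_stack_id]),
            normalization=np.array([self.normalization]),
        )

    @staticmethod
    def load(path) -> "SplinePSFModel":
        with np.load(path, allow_pickle=False) as f:
            return SplinePSFModel(
                f["coefficients"],
                tuple(f["knot_spacings_nm"]),
                tuple(f["origin_nm"]),
                float(f["wavelength_nm"][0]),
                str(f["source_stack_id"][0]),
                str(f["normalization"][0]),
            )


def _spline_coeff_pass(values: np.ndarray, axis: int) -> np.ndarray:
    """One separable natural-cubic-spline pass along ``axis``.

    Returns the piecewise-polynomial coefficients with two new leading axes
    ``(4, n-1)`` in scipy's descending-power convention.
    """
    n = values.shape[axis]
    cs = CubicSpline(np.arange(n), values, axis=axis, bc_type="natural")
    return cs.c


def build_spline_model(stack: PSFStack, source_stack_id: str = "") -> SplinePSFModel:
    """Tensor-product tricubic model of a detector-resolution stack.

    Three separable 1D natural-spline passes (x, then y, then z) yield the 64
    polynomial coefficients per cell; the result interpolates the stack
    exactly at every knot and is C² across cell boundaries.
    """
    v = stack.values
    nz, ny, nx = v.shape
    if nz < 4 or ny < 4 or nx < 4:
        raise ConfigurationError(
            f"stack too small for a cubic model: {v.shape} (need >= 4 per axis)"
        )
    cx = _spline_coeff_pass(v, axis=2)          # (4, nx-1, nz, ny)
    cy = _spline_coeff_pass(cx, axis=3)         # (4, ny-1, 4, nx-1, nz)
    cz = _spline_coeff_pass(cy, axis=4)         # (4, nz-1, 4, ny-1, 4, nx-1)
    C = np.transpose(cz, (1, 3, 5, 0, 2, 4))    # (nz-1, ny-1, nx-1, az, ay, ax)
    C = C[..., ::-1, ::-1, ::-1]                # descending -> ascending powers
    z0 = float(stack.z_positions_nm[0])
    lat0 = -((nx - 1) / 2.0) * stack.pixel_size_nm
    return SplinePSFModel(
        np.ascontiguousarray(C),
        knot_spacings_nm=(stack.z_step_nm, stack.pixel_size_nm, stack.pixel_size_nm),
        origin_nm=(z0, lat0, lat0),
        wavelength_nm=stack.wavelength_nm,
        source_stack_id=source_stack_id,
        normalization=stack.normalization,
    )


# ---------------------------------------------------------------------------
# forward model and information bounds
# ---------------------------------------------------------------------------

def _patch_knot_coords(
    model: SplinePSFModel, theta: FitParameters, patch_shape: tuple[int, int]
) -> np.ndarray:
    """Spline coordinates (knot units) of every pixel of a centered patch."""
    nz, ny, nx = model.n_knots
    h, w = patch_shape
    dz, dy, dx = model.knot_spacings_nm
    rows = np.arange(h) + (ny - h) / 2.0
    cols = np.arange(w) + (nx - w) / 2.0
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    pts = np.empty((h * w, 3))
    pts[:, 0] = (theta.z_nm - model.origin_nm[0]) / dz
    pts[:, 1] = yy.ravel() - theta.y_nm / dy
    pts[:, 2] = xx.ravel() - theta.x_nm / dx
    return pts


def evaluate_psf(
    model: SplinePSFModel,
    theta: FitParameters,
    patch_shape: tuple[int, int] = (13, 13),
) -> tuple[np.ndarray, np.ndarray]:
    """Expected image and its gradient w.r.t. all five parameters.

    Returns ``(mu (h, w), grad (h, w, 5))`` with parameter order
    (x, y, z, photons, background); gradients are analytic derivatives of the
    spline polynomial (nm and count units).
    """
    pts = _patch_knot_coords(model, theta, patch_shape)
    S, dS = model.evaluate(pts)
    dz_nm, dy_nm, dx_nm = model.knot_spacings_nm
    h, w = patch_shape
    mu = (theta.photons * S + theta.background).reshape(h, w)
    grad = np.empty((h * w, 5))
    grad[:, 0] = -theta.photons * dS[:, 2] / dx_nm
    grad[:, 1] = -theta.photons * dS[:, 1] / dy_nm
    grad[:, 2] = theta.photons * dS[:, 0] / dz_nm
    grad[:, 3] = S
    grad[:, 4] = 1.0
    return mu, grad.reshape(h, w, 5)


def fisher_information(
    model: SplinePSFModel,
    theta: FitParameters,
    patch_shape: tuple[int, int] = (13, 13),
) -> np.ndarray:
    """5x5 Poisson Fisher information matrix (symmetric PSD)."""
    mu, grad = evaluate_psf(model, theta, patch_shape)
    if np.any(mu <= 0):
        raise ModelValidityError(
            "expected image contains nonpositive rates; the model is not a "
            "valid Poisson mean at this theta"
        )
    G = grad.reshape(-1, 5)
    I = (G / mu.reshape(-1, 1)).T @ G
    return 0.5 * (I + I.T)


def crlb(
    model: SplinePSFModel,
    theta: FitParameters,
    patch_shape: tuple[int, int] = (13, 13),
) -> CRLBResult:
    """Cramér–Rao lower-bound standard deviations for each parameter."""
    I = fisher_information(model, theta, patch_shape)
    cond = np.linalg.cond(I)
    if not np.isfinite(cond) or cond > 1e14:
        raise DegeneracyError(
            f"Fisher information matrix is singular (condition number {cond:.3e})"
        )
    variances = np.diag(np.linalg.inv(I))
    return CRLBResult(*np.sqrt(np.maximum(variances, 0.0)))
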