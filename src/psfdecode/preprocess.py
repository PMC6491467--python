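"""Raw frames to filtered, normalized molecule patches.

This is the shared input pathway for both networks: molecules are detected
and localized in 2D with an isotropic Gaussian least-squares fit, cropped to
13 x 13 pixel patches, screened by the neighbor-distance and PSF-width
rules, and finally zero-centered and scaled to unit Euclidean norm.

Coordinate convention: pixel indices are 0-based, the frame origin is the
center of the top-left pixel, and a localization at a pixel center has
fractional part .0.  Crops are centered on the nearest-pixel position of the
2D localization — no subpixel re-interpolation, so patches keep the
pixelation jitter the networks must learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.optimize import least_squares

from .config import ConfigurationError

__all__ = [
    "Candidate",
    "MoleculeImage",
    "FilterRules",
    "DegenerateInputError",
    "detect_and_localize_2d",
    "crop_and_filter",
    "normalize_patch",
    "photon_band_filter",
]


class DegenerateInputError(ValueError):
    """A patch has no contrast and cannot be normalized."""


@dataclass
class Candidate:
    """One 2D-localized spot before filtering (pixel units)."""

    x_px: float
    y_px: float
    amplitude: float
    sigma_px: float
    offset: float
    photons: float

    def sigma2_nm(self, pixel_size_nm: float) -> float:
        """Fitted PSF width statistic 2*sigma, in nm."""
        return 2.0 * self.sigma_px * pixel_size_nm


@dataclass
class MoleculeImage:
    """A cropped single-molecule patch with photometry and provenance."""

    patch: np.ndarray
    frame_index: int
    x0_px: int
    y0_px: int
    x_px: float
    y_px: float
    photons: float
    sigma2_nm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        h, w = self.patch.shape
        if h != w or h % 2 != 1:
            raise ValueError("patch must be square with odd side")
        if self.photons < 0:
            raise ValueError("photons must be nonnegative")

    @property
    def normalized(self) -> np.ndarray:
        return normalize_patch(self.patch)


@dataclass(frozen=True)
class FilterRules:
    """Screening rules applied to detected molecules."""

    pixel_size_nm: float = 100.0
    min_separation_nm: float = 1000.0
    max_width_2sigma_nm: float = 400.0
    patch_size_px: int = 13
    photon_range: tuple[float, float] | None = None


def _fit_gaussian(window: np.ndarray, x0: float, y0: float) -> tuple[float, ...]:
    """Isotropic 2D Gaussian + constant offset, least squares.

    Returns (amplitude, x, y, sigma, offset) in window pixel coordinates.
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    data = window.ravel()
    offset0 = float(np.median(window))
    amp0 = max(float(window.max() - offset0), 1e-3)

    def residuals(p):
        a, x, y, s, off = p
        model = a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * s**2)) + off
        return model.ravel() - data

    res = least_squares(
        residuals,
        x0=[amp0, x0, y0, 1.3, offset0],
        bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, w, h, w, np.inf]),
        max_nfev=200,
    )
    a, x, y, s, off = res.x
    return float(a), float(x), float(y), float(abs(s)), float(off)


def detect_and_localize_2d(
    frame: np.ndarray,
    intensity_threshold: float | None = None,
    fit_window_px: int = 11,
) -> list[Candidate]:
    """Find and localize molecules in one frame.

    Local maxima above ``intensity_threshold`` (default: background median
    plus five background standard deviations, Poisson-estimated) are refined
    with an isotropic 2D Gaussian fit; photons are estimated as
    ``2 pi A sigma^2`` in pixel units.  An empty frame yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    bg = float(np.median(frame))
    if intensity_threshold is None:
        intensity_threshold = bg + 5.0 * np.sqrt(max(bg, 1.0))
    peaks = (frame == maximum_filter(frame, size=5)) & (frame > intensity_threshold)
    half = fit_window_px // 2
    out: list[Candidate] = []
    for y, x in np.argwhere(peaks):
        lo_y, hi_y = y - half, y + half + 1
        lo_x, hi_x = x - half, x + half + 1
        if lo_y < 0 or lo_x < 0 or hi_y > frame.shape[0] or hi_x > frame.shape[1]:
            continue  # cannot fit a full window; the crop filter would drop it anyway
        window = frame[lo_y:hi_y, lo_x:hi_x]
        a, fx, fy, s, off = _fit_gaussian(window, float(x - lo_x), float(y - lo_y))
        out.append(
            Candidate(
                x_px=lo_x + fx,
                y_px=lo_y + fy,
                amplitude=a,
                sigma_px=s,
                offset=off,
                photons=float(2.0 * np.pi * a * s**2),
            )
        )
    return out


def crop_and_filter(
    frame: np.ndarray,
    candidates: list[Candidate],
    rules: FilterRules,
    frame_index: int = 0,
    provenance: str = "",
) -> tuple[list[MoleculeImage], list[tuple[Candidate, str]]]:
    """Crop surviving candidates to patches; reject by the screening rules.

    Rules (applied as independent screens on the full candidate list, so
    their order cannot matter): every member of a pair closer than
    ``min_separation_nm`` is removed; fitted widths 2*sigma above
    ``max_width_2sigma_nm`` are removed; patches clipped by the frame edge
    are removed; an optional photon band is enforced.  Rejects are returned
    with a reason code.
    """
    frame = np.asarray(frame, dtype=float)
    n = len(candidates)
    reasons: dict[int, str] = {}
    # neighbor rule: both members of any close pair go
    min_sep_px = rules.min_separation_nm / rules.pixel_size_nm
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(
                candidates[i].x_px - candidates[j].x_px,
                candidates[i].y_px - candidates[j].y_px,
            )
            if d < min_sep_px:
                reasons.setdefault(i, "too_close")
                reasons.setdefault(j, "too_close")
    # width rule
    for i, c in enumerate(candidates):
        if c.sigma2_nm(rules.pixel_size_nm) > rules.max_width_2sigma_nm:
            reasons.setdefault(i, "too_wide")
    # photon band
    if rules.photon_range is not None:
        lo, hi = rules.photon_range
        for i, c in enumerate(candidates):
            if not lo <= c.photons <= hi:
                reasons.setdefault(i, "photons_out_of_range")
    # edge rule + crop
    half = rules.patch_size_px // 2
    kept: list[MoleculeImage] = []
    rejected: list[tuple[Candidate, str]] = []
    for i, c in enumerate(candidates):
        if i in reasons:
            rejected.append((c, reasons[i]))
            continue
        x0, y0 = int(round(c.x_px)), int(round(c.y_px))
        if (
            y0 - half < 0
            or x0 - half < 0
            or y0 + half + 1 > frame.shape[0]
            or x0 + half + 1 > frame.shape[1]
        ):
            rejected.append((c, "edge_clipped"))
            continue
        patch = frame[y0 - half : y0 + half + 1, x0 - half : x0 + half + 1].copy()
        kept.append(
            MoleculeImage(
                patch=patch,
                frame_index=frame_index,
                x0_px=x0,
                y0_px=y0,
                x_px=c.x_px,
                y_px=c.y_px,
                photons=c.photons,
                sigma2_nm=c.sigma2_nm(rules.pixel_size_nm),
                provenance=provenance,
            )
        )
    return kept, rejected


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Zero-center the patch, then scale to unit Euclidean norm.

    Idempotent, and invariant to affine rescaling of the input
    (``a * patch + b`` maps to the same output for a > 0).
    """
    patch = np.asarray(patch, dtype=float)
    centered = patch - patch.mean()
    norm = np.linalg.norm(centered)
    if norm < 1e-12:
        raise DegenerateInputError("constant patch cannot be normalized")
    return centered / norm


def save_molecules(molecules: list[MoleculeImage], path) -> None:
    """Molecule container: TIFF pages of raw patches plus a CSV index."""
    from pathlib import Path

    import pandas as pd
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.stack([m.patch for m in molecules]).astype(np.float32),
        photometric="minisblack",
    )
    pd.DataFrame(
        [
            {
                "frame": m.frame_index,
                "x0_px": m.x0_px,
                "y0_px": m.y0_px,
                "x_px": m.x_px,
                "y_px": m.y_px,
                "photons": m.photons,
                "sigma2_nm": m.sigma2_nm,
                "provenance": m.provenance,
            }
            for m in molecules
        ]
    ).to_csv(path.with_suffix(".csv"), index=False)


def load_molecules(path) -> list[MoleculeImage]:
    from pathlib import Path

    import pandas as pd
    import tifffile

    path = Path(path)
    patches = tifffile.imread(path).astype(float)
    if patches.ndim == 2:
        patches = patches[None]
    table = pd.read_csv(path.with_suffix(".csv"))
    return [
        MoleculeImage(
            patch=patches[i],
            frame_index=int(row.frame),
            x0_px=int(row.x0_px),
            y0_px=int(row.y0_px),
            x_px=float(row.x_px),
            y_px=float(row.y_px),
            photons=float(row.photons),
            sigma2_nm=float(row.sigma2_nm),
            provenance=str(row.provenance),
        )
        for i, row in table.reset_index(drop=True).iterrows()
    ]


def photon_band_filter(
    molecules: list[MoleculeImage], low: float, high: float
) -> tuple[list[MoleculeImage], list[MoleculeImage]]:
    """Partition molecules into the training band and the brighter remainder.

    Molecules inside ``[low, high]`` form the training partition; those above
    ``high`` the validation partition; dimmer molecules fall in neither.
    """
    if low > high:
        raise ConfigurationError("photon band: low must not exceed high")
    in_band = [m for m in molecules if low <= m.photons <= high]
    above = [m for m in molecules if m.photons > high]
    return in_band, above
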