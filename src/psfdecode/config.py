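"""Configuration objects shared across the simulation and fitting modules."""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the imaging system and sample.

    Parameters
    ----------
    numerical_aperture
        NA of the objective (dimensionless).
    immersion_index
        Refractive index of the immersion medium (e.g. 1.51 for oil).
    sample_index
        Refractive index of the sample medium (e.g. 1.33 for aqueous buffer).
    working_distance_um
        Nominal working distance of the objective, in micrometres.
    particle_depth_um
        Distance of the emitter from the coverslip, in micrometres.  A
        nonzero depth combined with an index mismatch introduces spherical
        aberration, which breaks the +z/-z symmetry of the defocused PSF.
    emission_wavelength_nm
        Emission wavelength in nanometres.
    """

    numerical_aperture: float = 1.45
    immersion_index: float = 1.51
    sample_index: float = 1.33
    working_distance_um: float = 130.0
    particle_depth_um: float = 1.0
    emission_wavelength_nm: float = 600.0

    def __post_init__(self) -> None:
        if not self.numerical_aperture > 0:
            raise ConfigurationError("numerical_aperture must be positive")
        if self.numerical_aperture > self.immersion_index:
            raise ConfigurationError(
                "numerical_aperture cannot exceed the immersion index"
            )
        if self.immersion_index < 1 or self.sample_index < 1:
            raise ConfigurationError("refractive indices must be >= 1")
        if not 300.0 < self.emission_wavelength_nm < 1000.0:
            raise ConfigurationError(
                "emission_wavelength_nm must lie in (300, 1000) nm"
            )
        if self.working_distance_um <= 0 or self.particle_depth_um < 0:
            raise ConfigurationError(
                "working distance must be positive and particle depth >= 0"
            )

    @property
    def matched_index(self) -> bool:
        return self.sample_index == self.immersion_index


@dataclass(frozen=True)
class GridConfig:
    """Sampling grids for the physical model and the detector.

    The physical PSF is evaluated on a fine lateral grid
    (``fine_resolution_nm``), then integrated over detector pixels
    (``pixel_size_nm``).  ``roi_size_px`` is the square window used for photon
    normalization, ``patch_size_px`` the square crop fed to the networks.
    """

    z_range_nm: float = 600.0
    z_step_nm: float = 20.0
    fine_resolution_nm: float = 5.0
    pixel_size_nm: float = 100.0
    roi_size_px: int = 24
    patch_size_px: int = 13

    def __post_init__(self) -> None:
        if self.z_range_nm <= 0 or self.z_step_nm <= 0:
            raise ConfigurationError("z_range_nm and z_step_nm must be positive")
        if abs(self.z_range_nm / self.z_step_nm
               - round(self.z_range_nm / self.z_step_nm)) > 1e-9:
            raise ConfigurationError("z_range_nm must be divisible by z_step_nm")
        ratio = self.pixel_size_nm / self.fine_resolution_nm
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "pixel_size_nm must be an integer multiple of fine_resolution_nm"
            )
        if self.patch_size_px % 2 != 1:
            raise ConfigurationError("patch_size_px must be odd")
        if self.roi_size_px < self.patch_size_px:
            raise ConfigurationError("roi_size_px must be >= patch_size_px")

    @property
    def binning_factor(self) -> int:
        return int(round(self.pixel_size_nm / self.fine_resolution_nm))

    @property
    def n_z_slices(self) -> int:
        return 2 * int(round(self.z_range_nm / self.z_step_nm)) + 1

    @property
    def detector_size_px(self) -> int:
        """Side of the simulated detector frame (one pixel beyond the ROI)."""
        return self.roi_size_px + 1
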