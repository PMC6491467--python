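"""Shared fixtures: PSF stacks, spline models and trained networks.

The expensive artifacts (diffraction stacks, training runs) are built once
per session at desk-scale sizes and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from psfdecode import networks as nw
from psfdecode import psf_sim as ps
from psfdecode import spline_model as sm
from psfdecode.config import GridConfig, OpticalConfig

WAVELENGTHS = (600.0, 700.0)


@pytest.fixture(scope="session")
def grid() -> GridConfig:
    return GridConfig()


@pytest.fixture(scope="session")
def optics() -> dict[int, OpticalConfig]:
    return {int(wl): OpticalConfig(emission_wavelength_nm=wl) for wl in WAVELENGTHS}


@pytest.fixture(scope="session")
def fine_stacks(optics, grid) -> dict[int, ps.PSFStack]:
    return {
        wl: ps.generate_psf_stack_cached(o, grid) for wl, o in optics.items()
    }


@pytest.fixture(scope="session")
def detector_stacks(fine_stacks, grid) -> dict[int, ps.PSFStack]:
    return {
        wl: ps.roi_normalized(ps.downsample_to_detector(s, grid), grid)
        for wl, s in fine_stacks.items()
    }


@pytest.fixture(scope="session")
def spline_models(detector_stacks) -> dict[int, sm.SplinePSFModel]:
    return {
        wl: sm.build_spline_model(s, source_stack_id=f"sim{wl}")
        for wl, s in detector_stacks.items()
    }


def make_color_dataset(optics, grid, fine_stacks, n_per_color, photons, z_range, seed):
    ds = ps.generate_benchmark_dataset(
        [optics[600], optics[700]],
        grid,
        n_per_color,
        photon_distribution=photons,
        z_distribution=(-z_range, z_range),
        rng_seed=seed,
        stacks=[fine_stacks[600], fine_stacks[700]],
    )
    X = nw.patches_to_inputs([img for img, _ in ds])
    y = np.array([t.color_label for _, t in ds])
    return X, y, [t for _, t in ds]


def make_axial_dataset(optics, grid, fine_stacks, wl, n, photons, z_range, seed,
                       z_distribution=None):
    ds = ps.generate_benchmark_dataset(
        [optics[wl]],
        grid,
        n,
        photon_distribution=photons,
        z_distribution=z_distribution or (-z_range, z_range),
        rng_seed=seed,
        stacks=[fine_stacks[wl]],
    )
    X = nw.patches_to_inputs([img for img, _ in ds])
    z = np.array([t.z_nm for _, t in ds])
    return X, z, [t for _, t in ds]


@pytest.fixture(scope="session")
def trained_classifier(optics, grid, fine_stacks):
    """Color classifier trained at desk scale (3000/class, 12 epochs)."""
    Xtr, ytr, _ = make_color_dataset(
        optics, grid, fine_stacks, 3000, (4500, 5500), 400.0, seed=101
    )
    Xv, yv, _ = make_color_dataset(
        optics, grid, fine_stacks, 400, (4500, 5500), 400.0, seed=102
    )
    net = nw.build_network(
        nw.NetworkSpec(hidden_layers=(256, 256, 128, 64), n_classes=2,
                       dropout_rate=0.5),
        seed=7,
    )
    net, log = nw.train_color_network(
        net,
        (Xtr, ytr),
        (Xv, yv),
        nw.TrainingConfig(initial_learning_rate=1e-4, batch_size=64,
                          max_epochs=12, seed=7),
    )
    return net, log


@pytest.fixture(scope="session")
def trained_axial(optics, grid, fine_stacks):
    """Axial regressors per dye (700 nm at full desk scale, 600 nm lighter)."""
    nets = {}
    for wl, n_train, epochs in ((700, 6000, 30), (600, 2500, 15)):
        Xtr, ztr, _ = make_axial_dataset(
            optics, grid, fine_stacks, wl, n_train, (4500, 5500), 600.0,
            seed=110 + wl,
        )
        Xv, zv, _ = make_axial_dataset(
            optics, grid, fine_stacks, wl, max(n_train // 10, 100),
            (4500, 5500), 600.0, seed=120 + wl,
        )
        net = nw.build_network(
            nw.NetworkSpec(hidden_layers=(512, 256, 128, 64), weight_decay=0.01),
            seed=3,
        )
        net, log = nw.train_axial_network(
            net,
            (Xtr, ztr),
            (Xv, zv),
            nw.TrainingConfig(initial_learning_rate=1e-3, batch_size=32,
                              max_epochs=epochs, decay_interval=2000,
                              plateau_patience=5, seed=3),
        )
        nets[wl] = (net, log)
    return nets
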