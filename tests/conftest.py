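"""Shared fixtures: small optical configs and the two optimized masks.

The optimized Tetrapod and EDOF masks are expensive to design, so they are
built once per session at the reduced scale used throughout the suite
(64 x 64 pupil, 2x padding) and shared between the design, evaluation and
acceptance tests.
"""

import numpy as np
import pytest

from psfdesign import (
    NoiseModel,
    OpticalConfig,
    OptimizeSettings,
    PhaseMask,
    optimize_edof,
    optimize_tetrapod,
)


@pytest.fixture(scope="session")
def cfg64() -> OpticalConfig:
    return OpticalConfig(grid_n=64, pad_factor=2)


@pytest.fixture(scope="session")
def cfg128() -> OpticalConfig:
    return OpticalConfig(grid_n=128, pad_factor=2)


@pytest.fixture(scope="session")
def zero_mask64(cfg64) -> PhaseMask:
    return PhaseMask.zero(cfg64)


@pytest.fixture(scope="session")
def design_noise() -> NoiseModel:
    return NoiseModel(photons=5000.0, background=10.0)


@pytest.fixture(scope="session")
def tetrapod64(cfg64, design_noise):
    """CRLB-optimized mask over +/-20 um (300 iterations, seeded)."""
    settings = OptimizeSettings(
        iterations=300, step_size=0.1, seed=1, z_range=(-20.0, 20.0), n_z=20
    )
    mask, history = optimize_tetrapod(cfg64, settings, design_noise)
    return mask, history, settings


@pytest.fixture(scope="session")
def edof64(cfg64):
    """Gaussian-target EDOF mask over +/-30 um (300 iterations, seeded)."""
    settings = OptimizeSettings(
        iterations=300, step_size=0.1, seed=1, z_range=(-30.0, 30.0), n_z=30
    )
    mask, history = optimize_edof(cfg64, settings)
    return mask, history, settings
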