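"""Shared fixtures: small cubes and a reduced synthetic benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from cannaspec import synthetic_data as sd
from cannaspec.cube_io import HyperspectralCube, default_wavelength_grid


@pytest.fixture(scope="session")
def wavelengths():
    return default_wavelength_grid()


@pytest.fixture
def small_cube(wavelengths):
    """10 x 12 x 150 cube with reproducible random reflectance."""
    rng = np.random.default_rng(7)
    data = rng.uniform(0.05, 0.9, size=(10, 12, 150))
    return HyperspectralCube(
        data, wavelengths, metadata={"sample_id": "toy", "drying_method": "hot_air", "day": 0.0}
    )


@pytest.fixture(scope="session")
def mini_benchmark():
    """Reduced benchmark (2 cubes per condition) shared across test modules.

    Small enough to build in seconds, big enough that every quality class
    is populated and the pipeline is end-to-end exercisable.
    """
    table, truths = sd.benchmark_spectrum_table(n_per_condition=2, seed=42)
    return table, truths
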