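import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from atriascar import ContrastKinetics, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom shared across tests (seed 42)."""
    config = PhantomConfig(seed=42)
    volumes, truth = generate_phantom(config)
    return config, volumes, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free phantom with ideal geometry (no wall-thickness variation,
    no segmentation error) at fine spacing: the crosstalk-free regime where
    every face value is exactly its compartment intensity."""
    config = PhantomConfig(
        grid_shape=(154, 154, 154),
        spacing_mm=(0.45,) * 3,
        shell_center_mm=(34.4,) * 3,
        shell_radii_mm=(24.0, 22.0, 20.0),
        wall_thickness_mm=4.0,
        wall_thickness_variation_mm=0.0,
        segmentation_error_mm=0.0,
        appendage_amp_frac=0.0,
        pv_stub_amp_frac=0.0,
        kinetics=ContrastKinetics(noise_sigma=0.0),
        seed=7,
    )
    volumes, truth = generate_phantom(config)
    return config, volumes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
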