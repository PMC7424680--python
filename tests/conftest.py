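import numpy as np
import pytest

from dapd.fixtures import (PopulationSpec, RosetteSpec, generate_population,
                           generate_rosette_image)


@pytest.fixture(scope="session")
def small_population():
    """25 plants, balanced integer shifts in [-3, 3], default noise."""
    spec = PopulationSpec(n_plants=25, shift_dist=("balanced", -3, 3), seed=42)
    dataset, shifts = generate_population(spec)
    return dataset, shifts


@pytest.fixture(scope="session")
def clean_population():
    """Noise-free, homogeneous-coefficient population with known shifts."""
    spec = PopulationSpec(
        n_plants=22, shift_dist=("balanced", -5, 5), a_dist=(0.9, 0.0),
        b_dist=(0.085, 0.0), leaf_noise_cv=0.0, area_noise_cv=0.0,
        diurnal_amplitude=0.0, missing_rate=0.0, seed=7)
    return generate_population(spec)


@pytest.fixture(scope="session")
def rosette_six():
    spec = RosetteSpec(n_leaves=6, overlap_fraction=0.2, background="soil")
    rgb, truth = generate_rosette_image(spec, seed=3)
    return spec, rgb, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
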