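import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppixmargin import (
    DatasetSpec,
    ExcitationChannel,
    TissueClassParams,
    default_references,
    make_wavelength_grid,
    simulate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    """The standard 435-840 nm / 900-point emission grid."""
    return make_wavelength_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast pipeline tests."""
    return make_wavelength_grid(435.0, 840.0, 120)


@pytest.fixture(scope="session")
def refs(grid):
    return default_references(grid)


@pytest.fixture(scope="session")
def small_refs(small_grid):
    return default_references(small_grid)


@pytest.fixture(scope="session")
def small_channels():
    """Three-LED protocol with few frames, for speed."""
    return (
        ExcitationChannel(center_nm=385, irradiance=1.0, n_frames=2),
        ExcitationChannel(center_nm=405, irradiance=0.375, n_frames=3),
        ExcitationChannel(center_nm=420, irradiance=0.625, n_frames=2),
    )


@pytest.fixture(scope="session")
def tiny_dataset(small_grid, small_refs, small_channels):
    """18-sample four-class cohort on the coarse grid."""
    spec = DatasetSpec(class_counts={"core": 4, "hd_margin": 6, "ld_margin": 4, "healthy": 4},
                       n_patients=5, seed=42)
    return simulate_dataset(spec, channels=small_channels, grid=small_grid,
                            refs=small_refs)


def noiseless_params(label="core", ppix=1.0, f620=0.0, af=0.0, ambient=0.0):
    return TissueClassParams(label, ppix_amount=ppix, f620=f620, af_amount=af,
                             dispersion=0.0, noise_sd=0.0, ambient_level=ambient)


@pytest.fixture
def make_noiseless_params():
    return noiseless_params
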