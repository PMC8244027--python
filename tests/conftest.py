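import numpy as np
import pytest

from rsfavasc import CohortSpec, generate_modality_maps, generate_spatial_sources, generate_subjects


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort kept small enough for fast unit tests."""
    return CohortSpec(n_subjects=120, grid_dims=(10, 10, 10), n_sources=3, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    subjects = generate_subjects(small_spec)
    truth = generate_spatial_sources(small_spec)
    maps = generate_modality_maps(subjects, truth, small_spec)
    return small_spec, subjects, truth, maps


@pytest.fixture(scope="session")
def desk_spec():
    """The default study conditions: 250 subjects, 16^3 grid, 4 sources."""
    return CohortSpec(seed=7)


@pytest.fixture(scope="session")
def desk_cohort(desk_spec):
    subjects = generate_subjects(desk_spec)
    truth = generate_spatial_sources(desk_spec)
    maps = generate_modality_maps(subjects, truth, desk_spec)
    return desk_spec, subjects, truth, maps


@pytest.fixture()
def rng():
    # fresh generator per test: no cross-test state leakage
    return np.random.default_rng(2024)
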