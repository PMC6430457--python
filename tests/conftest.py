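"""Shared fixtures: all test geometry is generated programmatically."""

import numpy as np
import pytest

from femoromorph import synthetic_femur as sf
from femoromorph.morphometry import measure_femur_detailed


@pytest.fixture(scope="session")
def mean_femur():
    """Mean-parameter synthetic femur: (mesh, ground truth)."""
    return sf.generate_femur_mesh(sf.mean_parameters())


@pytest.fixture(scope="session")
def mirrored_femur():
    """Left-side mean-parameter femur: (mesh, ground truth)."""
    return sf.generate_femur_mesh(sf.mean_parameters(side="left",
                                                     specimen_id="mean-left"))


@pytest.fixture(scope="session")
def mean_measurement(mean_femur):
    """Full-pipeline measurement of the mean femur (6 repeats, seed 42)."""
    mesh, _ = mean_femur
    return measure_femur_detailed(mesh, repeats=6, seed=42)


@pytest.fixture(scope="session")
def cylinder_mesh():
    return sf.make_cylinder_mesh(radius=14.0, length=440.0)


@pytest.fixture(scope="session")
def big_cohort():
    """Large calibration cohort (n = 1e5) from the default spec."""
    return sf.sample_cohort(sf.GeneratorSpec(n=100_000, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
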