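"""Shared fixtures: phantoms and cohorts are generated once per session."""

import numpy as np
import pytest

from molarmetrics.geometry import align_vertical
from molarmetrics.phantom import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def upright_phantom():
    """The reference phantom: a=10, b=12, c=150, no rotation."""
    return generate_phantom(PhantomSpec(a_px=10, b_px=12, c_px=150))


@pytest.fixture(scope="session")
def rotated_phantom():
    return generate_phantom(PhantomSpec(a_px=10, b_px=12, c_px=150, rotation_deg=25))


@pytest.fixture(scope="session")
def aligned_upright(upright_phantom):
    return align_vertical(upright_phantom.apical_mask, upright_phantom.coronal_mask)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-phantom cohort under the study conditions (for module tests)."""
    return generate_cohort(30, seed=7)


@pytest.fixture(scope="session")
def study_cohort():
    """The 100-phantom cohort used by the acceptance-style checks."""
    return generate_cohort(100, seed=1)


@pytest.fixture(scope="session")
def study_cohort_aligned(study_cohort):
    return [
        (ph, align_vertical(ph.apical_mask, ph.coronal_mask)) for ph in study_cohort
    ]


def random_mask(rng: np.random.Generator, shape=(32, 32), p=0.3) -> np.ndarray:
    return rng.random(shape) < p
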