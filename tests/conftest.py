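"""Shared fixtures: phantoms and assembled operators are expensive, so they
are built once per session at two resolutions — a coarse head phantom for
unit tests and the default-resolution phantom for the acceptance checks."""

import numpy as np
import pytest

from ocustim.phantom import (PhantomConfig, build_head_phantom,
                             build_sphere_phantom)
from ocustim.solver import ConductionOperator

#: Coarse settings keep unit tests fast while exercising the same code
#: paths (all structural shells present, both eyes, full catalog placeable).
COARSE = PhantomConfig(fine_size=4.5, coarse_size=11.0,
                       eye_surface_size=2.4, periocular_skin_size=2.4,
                       skin_surface_size=7.0, seed=7)


@pytest.fixture(scope="session")
def coarse_config():
    return COARSE


@pytest.fixture(scope="session")
def coarse_phantom():
    return build_head_phantom(COARSE)


@pytest.fixture(scope="session")
def coarse_operator(coarse_phantom):
    return ConductionOperator(coarse_phantom)


@pytest.fixture(scope="session")
def head_phantom():
    """Default-resolution phantom (the study conditions)."""
    return build_head_phantom(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def head_operator(head_phantom):
    return ConductionOperator(head_phantom)


@pytest.fixture(scope="session")
def small_sphere():
    return build_sphere_phantom(radius=40.0, target_size=5.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
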