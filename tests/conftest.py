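import numpy as np
import pytest
from hypothesis import settings

from genetrank import fixtures

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def path3():
    return fixtures.make_toy("path3")


@pytest.fixture(scope="session")
def path4():
    return fixtures.make_toy("path4_two_targets")


@pytest.fixture(scope="session")
def star():
    return fixtures.make_toy("star")


@pytest.fixture(scope="session")
def triangle():
    return fixtures.make_toy("triangle")


@pytest.fixture(scope="session")
def fig1_motif():
    return fixtures.make_toy("fig1_motif")


@pytest.fixture(scope="session")
def smallworld():
    """A mid-size seeded small-world instance shared across tests."""
    return fixtures.make_smallworld_instance(
        n=120, mean_degree=6, rewire_p=0.1, x_size=20, p_size=6, seed=7
    )


@pytest.fixture(scope="session")
def study_scale_instance():
    """Instance at the case study's proportions: |X|=227, |P|=41, n=1000."""
    return fixtures.make_smallworld_instance(
        n=1000, mean_degree=8, rewire_p=0.1, x_size=227, p_size=41, seed=11
    )
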