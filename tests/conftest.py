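import numpy as np
import pytest
from hypothesis import settings

from retflow import BeamGeometry, datasets

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def example_table():
    """Per-vessel table of the bundled single-subject room-air example."""
    return datasets.example_subject()


@pytest.fixture(scope="session")
def example_arteries(example_table):
    return example_table[example_table.vessel_type == "A"]


@pytest.fixture(scope="session")
def example_veins(example_table):
    return example_table[example_table.vessel_type == "V"]


@pytest.fixture
def geometry():
    """A convenient geometry with a round inter-beam angle."""
    return BeamGeometry(inter_beam_angle_rad=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(20150)
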