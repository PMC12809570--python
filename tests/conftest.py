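import numpy as np
import pytest

from memiso.core_model import MembraneComposition, default_lipid_specs
from memiso import synthetic as syn


@pytest.fixture(scope="session")
def specs():
    return default_lipid_specs()


@pytest.fixture(scope="session")
def tiny_composition(specs):
    """Three lipids per leaflet: enough structure for every metric at
    negligible cost."""
    return MembraneComposition(((specs["PYPE"], 2), (specs["POPE"], 1)))


def make_tiny_spec(tiny_composition, condition="cis", seed=1, n_frames=20, **kw):
    return syn.default_spec(
        condition,
        seed=seed,
        composition=tiny_composition,
        box=(20.0, 20.0, 60.0),
        n_frames=n_frames,
        **kw,
    )


@pytest.fixture(scope="session")
def tiny_built(tiny_composition):
    spec = make_tiny_spec(tiny_composition, thickness_sigma=0.0)
    return syn.build_membrane(spec)


@pytest.fixture(scope="session")
def full_built_cis():
    spec = syn.default_spec("cis", seed=42, thickness_sigma=0.0)
    return syn.build_membrane(spec)


@pytest.fixture(scope="session")
def tiny_trajectory(tiny_composition):
    spec = make_tiny_spec(tiny_composition, n_frames=30)
    return syn.simulate_trajectory(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
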