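import numpy as np
import pytest

import painmesh as pm


@pytest.fixture(scope="session")
def template83() -> pm.LandmarkFrame:
    return pm.make_template("bp4d83", seed=0)


@pytest.fixture(scope="session")
def mirror83() -> pm.MirrorMap:
    return pm.builtin_mirror_map("bp4d83")


@pytest.fixture(scope="session")
def basis83(template83, mirror83) -> pm.DeformationBasis:
    return pm.make_basis(template83, pm.AU_ALL_IDS, seed=0, mirror=mirror83)


@pytest.fixture(scope="session")
def tiny_dataset() -> list[pm.Segment]:
    """Six subjects x 4 short segments on the sparse topology; low noise."""
    cfg = pm.SimulationConfig(n_subjects=6, segment_seconds=4.0,
                              topology_id="bp4d83", noise_sd=0.005, seed=11)
    return pm.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
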