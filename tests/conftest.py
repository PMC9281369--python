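import numpy as np
import pytest

from g4validate.core import EnsembleBundle
from g4validate.synthetic import (SyntheticSpec, build_duplex_stem, build_ideal_g4,
                                  build_system, generate_fluctuating_trajectory)


@pytest.fixture(scope="session")
def ideal_g4():
    """Three stacked tetrads with both channel slots occupied."""
    return build_ideal_g4(n_tetrads=3, channel_ions=2)


@pytest.fixture(scope="session")
def duplex3():
    """Three-pair GC stem: pairs (1,6), (2,5), (3,4)."""
    return build_duplex_stem(3)


@pytest.fixture(scope="session")
def system_and_annotation():
    """Quadruplex-duplex system with ground-truth annotation (2 channel ions)."""
    return build_system(SyntheticSpec())


@pytest.fixture()
def static_traj(system_and_annotation):
    """Ten identical frames of the ideal system in an 80 Å box."""
    model, _ = system_and_annotation
    return generate_fluctuating_trajectory(model, {"all": 0.0}, 10, seed=0, box_edge=80.0)


@pytest.fixture(scope="session")
def single_model_bundle(system_and_annotation):
    model, _ = system_and_annotation
    return EnsembleBundle([model])


def rotation_matrix(seed: int = 7) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
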