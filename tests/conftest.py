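import numpy as np
import pytest

from symsurf import (
    BuildSpec,
    SasaConfig,
    StickinessScale,
    detect_point_group,
    make_cyclic,
    make_dihedral,
    make_monomer_control,
)
from symsurf.stickiness import STANDARD_LETTERS


@pytest.fixture(scope="session")
def c3():
    """Synthetic C3 trimer with its construction ground truth."""
    return make_cyclic(BuildSpec(n=3, chain_size=25, seed=11))


@pytest.fixture(scope="session")
def d4():
    """Synthetic D4 octamer with its construction ground truth."""
    return make_dihedral(BuildSpec(n=4, chain_size=25, seed=12))


@pytest.fixture(scope="session")
def d2():
    """Synthetic D2 tetramer with its construction ground truth."""
    return make_dihedral(BuildSpec(n=2, chain_size=25, seed=13))


@pytest.fixture(scope="session")
def monomer():
    """Monomer control: single chain plus a seeded random fold-1 axis."""
    return make_monomer_control(BuildSpec(n=1, chain_size=25, seed=14))


@pytest.fixture(scope="session")
def d4_solution(d4):
    return detect_point_group(d4[0])


@pytest.fixture(scope="session")
def fast_sasa():
    """Coarse quadrature for tests where absolute ASA accuracy is irrelevant."""
    return SasaConfig(sphere_points=240)


@pytest.fixture(scope="session")
def uniform_scale():
    return StickinessScale({letter: 0.42 for letter in STANDARD_LETTERS}, "constant test scale")


@pytest.fixture(scope="session")
def random_scale():
    rng = np.random.default_rng(99)
    vals = rng.normal(0.0, 0.8, size=20)
    return StickinessScale(dict(zip(STANDARD_LETTERS, vals.tolist())), "seeded synthetic scale")
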