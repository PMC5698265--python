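import numpy as np
import pytest

from stereovasc import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def box_region():
    return phantom.ReferenceRegion("box", (500.0, 500.0, 500.0))


@pytest.fixture(scope="session")
def sphere_region():
    return phantom.ReferenceRegion("sphere", (250.0,))


@pytest.fixture(scope="session")
def small_network(box_region):
    """~300 segments at 300 mm/mm^3 in a (500 μm)^3 box."""
    return phantom.generate_network(box_region, 3.0e-4, seed=42)


@pytest.fixture(scope="session")
def sphere_network(sphere_region):
    return phantom.generate_network(sphere_region, 3.0e-4, seed=43)


def random_profiles(rng, n, extent=400.0, rmin=1.0, rmax=6.0):
    """Random ellipse profiles scattered over a centred square extent."""
    from stereovasc.sectioning import Profile

    profs = []
    for k in range(n):
        b = rng.uniform(rmin, rmax)
        a = b * rng.uniform(1.0, 3.0)
        center = rng.uniform(-extent / 2, extent / 2, size=2)
        profs.append(Profile(center=center, semi_minor=b, semi_major=a,
                             angle=rng.uniform(0, np.pi),
                             segment_id=k))
    return profs
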