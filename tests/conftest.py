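import numpy as np
import pytest

from desqspr import sigma_profiles as sp
from desqspr import mixtures as mx
from desqspr import synthetic_data as syn


def make_random_profile(seed, n_points=51, span=1.0):
    """A random multi-peak σ-profile; span > 1 pushes mass outside the window."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(sp.SIGMA_MIN * span, sp.SIGMA_MAX * span, n_points)
    density = np.zeros_like(grid)
    for _ in range(rng.integers(1, 5)):
        c = rng.uniform(grid[0], grid[-1])
        w = rng.uniform(0.001, 0.006)
        density += rng.uniform(1, 50) * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return sp.SigmaProfile(name=f"rand-{seed}", sigma=grid, p=density,
                           grid_spacing=float(grid[1] - grid[0]))


def make_constituent(name, molar_mass, S, role="HBD"):
    return mx.Constituent(
        name=name, molar_mass=molar_mass, role=role,
        descriptors=sp.DescriptorVector(S=np.asarray(S, dtype=float)),
    )


@pytest.fixture
def gaussian_profile():
    """A 51-point Gaussian σ-profile spanning the full descriptor window."""
    grid = np.linspace(sp.SIGMA_MIN, sp.SIGMA_MAX, 51)
    p = 120.0 * np.exp(-0.5 * (grid / 0.008) ** 2)
    p = p / p.sum() * 120.0
    return sp.SigmaProfile(name="gauss", sigma=grid, p=p,
                           grid_spacing=float(grid[1] - grid[0]))


@pytest.fixture
def simple_constituents():
    """Three constituents with small-integer descriptor vectors."""
    return [
        make_constituent("a", 100.0, [1, 0, 0, 0, 2, 0, 0, 0, 0, 1], role="HBA"),
        make_constituent("b", 80.0, [0, 3, 0, 0, 0, 0, 1, 0, 0, 0]),
        make_constituent("c", 18.015, [0, 0, 0, 2, 0, 0, 0, 0, 4, 0], role="water"),
    ]


@pytest.fixture(scope="session")
def small_library():
    """The default synthetic screening library (28 formulations)."""
    return syn.synth_library(syn.SyntheticSpec(seed=0))
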