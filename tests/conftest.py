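"""Shared fixtures: all geometry is generated programmatically at test time."""

import numpy as np
import pytest
import trimesh

from fdpfit.phantom import PhantomSpec, generate_triad


def make_cube():
    """Unit cube as a welded 8-vertex, 12-face mesh."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return trimesh.Trimesh(vertices=box.vertices, faces=box.faces, process=False)


@pytest.fixture(scope="session")
def cube():
    return make_cube()


@pytest.fixture(scope="session")
def default_spec():
    """Phantom with a uniform 100 um horizontal margin misfit, noiseless."""
    return PhantomSpec(horizontal_extension=0.1)


@pytest.fixture(scope="session")
def noiseless_triad(default_spec):
    return generate_triad(default_spec)


@pytest.fixture(scope="session")
def fast_spec():
    """Coarser phantom for tests that run many pipelines."""
    return PhantomSpec(horizontal_extension=0.1, n_theta=96, n_axial=2)


def assert_monotone_history(result):
    """ICP residual histories must never increase."""
    h = result.residual_history
    assert all(a >= b - 1e-15 for a, b in zip(h, h[1:]))


def sample_with_moments(n: int, mean: float, sd: float, seed: int = 0):
    """A sample with *exactly* the requested mean and sample sd (ddof=1)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x
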