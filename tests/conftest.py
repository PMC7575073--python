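import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from reefcool import ReefGrid, flow_from_streamfunction


def uniform_grid(ny, nx, depth, dx=20.0, dy=None, label="test"):
    """All-wet rectangular grid of constant depth."""
    return ReefGrid(dx=dx, dy=dx if dy is None else dy,
                    depth=np.full((ny, nx), float(depth)), label=label)


def channel_grid(nx=100, ny=3, dx=20.0, depth=5.0, reef_cols=None):
    """Open 1-D channel; optionally a strip of reef-depth (2 m) columns."""
    d = np.full((ny, nx), float(depth))
    if reef_cols is not None:
        d[:, reef_cols] = 2.0
    return ReefGrid(dx=dx, dy=dx, depth=d, label="channel")


def sealed_basin_grid(depth=10.0, dx=40.0):
    """A single wet cell surrounded by land (a sealed basin)."""
    d = np.zeros((3, 3))
    d[1, 1] = depth
    return ReefGrid(dx=dx, dy=dx, depth=d, label="basin")


def steady_uniform_flow(grid, u, h, K=0.0, t_end=1e7):
    """Steady eastward transport u*h [m^2/s] as a streamfunction.

    ``u`` is the velocity [m/s] realised in cells of depth ``h`` [m]; in
    deeper cells the same depth-integrated transport moves slower.
    """
    _, yc = grid.corner_coords()
    return flow_from_streamfunction(grid, u * h * yc,
                                    times=np.array([0.0, t_end]), K=K)


def closed_gyre_flow(grid, strength, K=0.0, t_end=1e7):
    """Single non-divergent gyre with no transport through the domain edge."""
    xc, yc = grid.corner_coords()
    lx, ly = grid.nx * grid.dx, grid.ny * grid.dy
    psi = strength * np.sin(np.pi * xc / lx) * np.sin(np.pi * yc / ly)
    return flow_from_streamfunction(grid, psi, times=np.array([0.0, t_end]), K=K)


@pytest.fixture
def island_grid():
    from reefcool import make_island_reef
    return make_island_reef(50, 50, 40.0, island_radius=300.0,
                            reef_flat_width=200.0, seed=1)
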