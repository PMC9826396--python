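import numpy as np
import pytest

from gravnet.raster import RasterGrid
from gravnet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast study: 4 sites, coarse grid, few loci."""
    return SimulationConfig(
        seed=1, n_sites=4, inds_per_site=6, n_loci=200,
        grid_shape=(60, 60), noise_sd=0.1, site_sd=0.1,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full default-scale dataset, shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture()
def random_raster():
    rng = np.random.default_rng(7)
    return RasterGrid(rng.random((20, 20)), 1.0, (0.0, 20.0))


def exact_cells_crossed(grid, x0, y0, x1, y1):
    """Independent oracle: Liang-Barsky clipping of the open segment against
    every cell's open box; returns the set of (row, col) genuinely crossed."""
    s = grid.cell_size
    gx0, gy0 = grid.origin
    nrow, ncol = grid.shape
    out = set()
    for r in range(nrow):
        for c in range(ncol):
            xmin, xmax = gx0 + c * s, gx0 + (c + 1) * s
            ymax, ymin = gy0 - r * s, gy0 - (r + 1) * s
            dx, dy = x1 - x0, y1 - y0
            t0, t1 = 0.0, 1.0
            reject = False
            for p, q in ((-dx, x0 - xmin), (dx, xmax - x0), (-dy, y0 - ymin), (dy, ymax - y0)):
                if p == 0:
                    if q < 0:
                        reject = True
                        break
                else:
                    t = q / p
                    if p < 0:
                        t0 = max(t0, t)
                    else:
                        t1 = min(t1, t)
            if not reject and t1 - t0 > 1e-12:
                out.add((r, c))
    return out
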