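import numpy as np
import pytest

import petdelin as p
from petdelin.core import GridSpec


@pytest.fixture(scope="session")
def fine_grid():
    """The 2.036 mm in-plane lattice, truncated axially for speed."""
    return p.standard_grid(400, nz=31)


@pytest.fixture(scope="session")
def coarse_grid():
    return p.standard_grid(200, nz=31)


@pytest.fixture(scope="session")
def small_grid():
    """Tiny isotropic-ish lattice for fast synthetic constructions."""
    return GridSpec((40, 40, 24), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def reduced_run(tmp_path_factory):
    """Reduced simulated benchmark shared by harness and acceptance tests.

    Seven-sphere cylinder phantom, both contrasts, all four protocol presets,
    one count level, three replicates, 200 matrix, EQ.PET on; seed fixed.
    """
    grid = p.ExperimentGrid(
        phantom="spheres",
        contrasts=(4.0, 8.0),
        protocols=("OP", "OP+TOF", "PSF", "PSF+TOF"),
        count_levels=(3.0e7,),
        replicates=3,
        matrices=(200,),
        methods=("T40", "T50", "CT", "AT40", "AT50"),
        eqpet=True,
    )
    out = tmp_path_factory.mktemp("reduced_run")
    return p.run_experiment(grid, out_dir=out, base_seed=7)


def brute_force_sphere_count(center, diameter, grid, origin=None):
    """Independent center-inclusion scan over every voxel of the grid."""
    if origin is None:
        origin = grid.centered_origin()
    n = 0
    r2 = (diameter / 2.0) ** 2
    for i in range(grid.matrix[0]):
        x = origin[0] + i * grid.voxel_size[0]
        for j in range(grid.matrix[1]):
            y = origin[1] + j * grid.voxel_size[1]
            for k in range(grid.matrix[2]):
                z = origin[2] + k * grid.voxel_size[2]
                if (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= r2:
                    n += 1
    return n
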