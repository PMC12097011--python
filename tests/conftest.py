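"""Shared fixtures: small phantoms and analytic shapes, generated at test time."""

import numpy as np
import pytest

from hepamorph.grid import VoxelGrid
import hepamorph.phantom as ph


@pytest.fixture(scope="session")
def default_phantom():
    """A 96³ phantom with default study-condition parameters."""
    cfg = ph.PhantomConfig(shape=(96, 96, 96), seed=11)
    truth, gray = ph.generate_phantom(cfg)
    return cfg, truth, gray


@pytest.fixture(scope="session")
def ball_grid():
    """A rasterized ball of radius 20 µm on a 96³ 1-µm grid."""
    x, y, z = np.meshgrid(*(np.arange(96),) * 3, indexing="ij")
    m = (x - 48) ** 2 + (y - 48) ** 2 + (z - 48) ** 2 <= 20**2
    return VoxelGrid(m.astype(np.int8), (1.0, 1.0, 1.0), kind="labels")


@pytest.fixture()
def flush_cylinder():
    """A radius-5 µm cylinder spanning the full x extent (L = 100 µm)."""
    m = np.zeros((100, 40, 40), dtype=bool)
    yy, zz = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
    m[:, (yy - 20) ** 2 + (zz - 20) ** 2 <= 25] = True
    return VoxelGrid(m.astype(np.int8), (1.0, 1.0, 1.0), kind="labels")
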