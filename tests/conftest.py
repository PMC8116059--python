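import numpy as np
import pytest

from memsolv import descriptors, grid, membrane


@pytest.fixture(scope="session")
def flat_mixed():
    """Flat mixed bilayer, 100 lipids/leaflet, 1/3 DL, leaflets assigned."""
    cfg = membrane.generate_flat_bilayer(100, 1 / 3, 38.0, seed=11)
    return descriptors.assign_leaflets(cfg)


@pytest.fixture(scope="session")
def flat_po():
    cfg = membrane.generate_flat_bilayer(64, 0.0, 38.0, seed=7)
    return descriptors.assign_leaflets(cfg)


@pytest.fixture
def unit_grid():
    def make(cfg, cell_edge=1.0, stamp_radius=2.6):
        return grid.GridSpec.for_box(cfg.box, cell_edge, stamp_radius)

    return make


def gaussian_bump(center, amplitude, sigma, box, baseline=0.0):
    """Periodic-aware 2D Gaussian field helper used across planted fixtures."""
    cx, cy = center
    lx, ly = box[0], box[1]

    def field(x, y):
        dx = x - cx - lx * np.round((x - cx) / lx)
        dy = y - cy - ly * np.round((y - cy) / ly)
        return baseline + amplitude * np.exp(-(dx**2 + dy**2) / (2 * sigma**2))

    return field
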