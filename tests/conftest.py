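import numpy as np
import pytest

from cnvquant.imaging import ImageSpec, rasterize_tree
from cnvquant.vessels import Segment, VesselTree, generate_vessel_tree


@pytest.fixture(scope="session")
def trunk_tree() -> VesselTree:
    """A single horizontal trunk across the field (off the exact centreline,
    which coincides with a box-grid boundary and is a degenerate alignment)."""
    segs = [Segment(start=(0.8, 2.2), end=(3.7, 2.2), caliber_um=40.0, generation=0, parent=-1)]
    return VesselTree(segments=segs, root_xy=(0.8, 2.2), field_mm=4.5, seed=0)


@pytest.fixture(scope="session")
def branched_tree() -> VesselTree:
    return generate_vessel_tree(0.6, seed=3)


@pytest.fixture(scope="session")
def noise_free_spec() -> ImageSpec:
    return ImageSpec(width_px=320, height_px=320, noise_level=0.0, background_level=0.1)


@pytest.fixture(scope="session")
def trunk_image(trunk_tree, noise_free_spec):
    return rasterize_tree(trunk_tree, noise_free_spec, seed=0)


def brute_force_box_counts(mask: np.ndarray, r: int, oy: int, ox: int):
    """Independent oracle: enumerate every box of the periodically shifted
    grid and count occupied boxes plus the mass list (occupied only)."""
    h, w = mask.shape
    shifted = np.roll(np.roll(mask, oy, axis=0), ox, axis=1)
    n_by = (h + r - 1) // r
    n_bx = (w + r - 1) // r
    masses = []
    for by in range(n_by):
        for bx in range(n_bx):
            m = shifted[by * r : (by + 1) * r, bx * r : (bx + 1) * r].sum()
            if m > 0:
                masses.append(int(m))
    return len(masses), sorted(masses)
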