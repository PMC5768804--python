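import numpy as np
import pytest

import rfasim as rf
from rfasim.phantom import Grid, TissueProperties, build_phantom, make_tumor_mask


@pytest.fixture(scope="session")
def small_phantom() -> rf.Phantom:
    """24^3 phantom at 3 mm with a central tumor and one lateral vessel."""
    return rf.make_default_phantom(shape=(24, 24, 24), spacing=(3.0, 3.0, 3.0),
                                   tumor_radius=7.0, vessel_offset=12.0)


@pytest.fixture()
def simple_needle(small_phantom) -> rf.NeedleGeometry:
    c = small_phantom.tumor.centroid()
    return rf.make_simple_needle(c, c + np.array([0.0, 0.0, 30.0]))


@pytest.fixture()
def fast_protocol() -> rf.Protocol:
    return rf.Protocol((rf.ProtocolPhase(60.0, "constant_power", 20.0),), gaussian_sigma_mm=3.0)


def uniform_phantom(n: int, h: float, perfusion: float = 0.0, crop_radius=None,
                    tumor_radius: float = 2.0) -> rf.Phantom:
    """Homogeneous full-grid phantom (tiny anchor tumor) for solver oracles."""
    grid = Grid((n, n, n), (h, h, h))
    lo, hi = grid.bounds()
    center = (lo + hi) / 2.0
    props = TissueProperties(1060.0, 3600.0, 0.512, perfusion)
    tumor = make_tumor_mask(grid, center, tumor_radius)
    return build_phantom(grid, tumor, healthy=props, tumor_props=props,
                         vessel_props=props, crop_radius=crop_radius)


def grid_center(phantom: rf.Phantom) -> np.ndarray:
    lo, hi = phantom.grid.bounds()
    return (lo + hi) / 2.0
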