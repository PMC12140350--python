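import numpy as np
import pytest

from liqchan.geometry_model import ChannelGeometry
from liqchan.synthetic_scenes import SceneConfig, SyntheticCell


@pytest.fixture
def geom30() -> ChannelGeometry:
    return ChannelGeometry(width_w=30.0)


@pytest.fixture
def stack_config(geom30) -> SceneConfig:
    """Default imaging config for a short 30 um channel segment."""
    return SceneConfig(geometry=geom30, baseline_h=2.0, fov_y=60.0, seed=11)


@pytest.fixture
def clean_stack_config(geom30) -> SceneConfig:
    """Noise- and blur-free variant for exact round-trip checks."""
    return SceneConfig(
        geometry=geom30, baseline_h=2.0, fov_y=60.0, seed=11, noise_sd=0.0, psf_sigma=0.0
    )


@pytest.fixture
def bump_cell() -> SyntheticCell:
    """A single immobile cell deforming the interface to 5 um."""
    return SyntheticCell(position=(0.0, 30.0), body_height=5.0)


def circumcircle(p1, p2, p3):
    """Independent three-point circumcircle oracle (perpendicular bisectors)."""
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    if d == 0:
        return None, np.inf
    ux = (
        (x1**2 + y1**2) * (y2 - y3)
        + (x2**2 + y2**2) * (y3 - y1)
        + (x3**2 + y3**2) * (y1 - y2)
    ) / d
    uy = (
        (x1**2 + y1**2) * (x3 - x2)
        + (x2**2 + y2**2) * (x1 - x3)
        + (x3**2 + y3**2) * (x2 - x1)
    ) / d
    r = np.hypot(x1 - ux, y1 - uy)
    return (ux, uy), r
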