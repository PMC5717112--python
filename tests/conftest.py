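import numpy as np
import pytest

from flow4d.atlas import SharedGeometry
from flow4d.core import AortaMask
from flow4d.phantom import PhantomConfig, generate_phantom
from flow4d.segment import extract_wall


@pytest.fixture(scope="session")
def oracle_phantom():
    """Steady Poiseuille tube at the default acquisition grid.

    R = 10 mm, v_max = 1 m/s, spacing 2.0 x 1.7 x 2.2 mm^3; the analytic
    wall shear stress is 2*mu*v_max/R = 0.64 Pa (mu = 3.2 cP) and the
    viscous energy loss is 2*pi*mu*L*v_max^2 for the tube length L.
    """
    cfg = PhantomConfig(n_frames=1, temporal_envelope=[1.0])
    field, mag, truth = generate_phantom(cfg)
    wall = extract_wall(truth.mask)
    return cfg, field, mag, truth, wall


@pytest.fixture(scope="session")
def small_phantom():
    """Small, quick Poiseuille phantom with a systolic envelope."""
    cfg = PhantomConfig(
        grid_shape=(36, 42, 24),
        tube_radius=8.0,
        n_frames=6,
        v_max=1.0,
        seed=11,
    )
    field, mag, truth = generate_phantom(cfg)
    return cfg, field, mag, truth


@pytest.fixture(scope="session")
def cube_shared():
    """Minimal shared geometry (a solid cube) for location-indexed stats."""
    mask = AortaMask(np.ones((10, 10, 10), bool), (2.0, 2.0, 2.0))
    wall = extract_wall(mask)
    return SharedGeometry(
        mask=mask,
        wall=wall,
        inclusion_fraction=1.0,
        reference_index=0,
        rigid_transforms=[],
    )
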