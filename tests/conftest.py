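"""Shared fixtures: synthetic cases are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ablamargin.grid import Grid, LabelMask
from ablamargin.phantom import (
    PhantomSpec,
    WarpSpec,
    generate_phantom,
    scaled_spec,
)
from ablamargin.registration import biomech_register


@pytest.fixture(scope="session")
def default_case():
    """Full-size (96 mm)^3 phantom with the default 8 mm warp."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_registration(default_case):
    """Biomechanical registration of the default case (rigid, total DVF)."""
    return biomech_register(
        default_case.pre_volume,
        default_case.pre_masks["liver"],
        default_case.post_volume,
        default_case.post_masks["liver"],
    )


@pytest.fixture(scope="session")
def small_case():
    """(64 mm)^3 phantom, anatomy and warp scaled down accordingly."""
    return generate_phantom(scaled_spec(seed=11, shape=64))


@pytest.fixture(scope="session")
def small_still_case():
    """(64 mm)^3 phantom with the warp disabled (pre == post geometry)."""
    return generate_phantom(scaled_spec(seed=12, shape=64, warp_amplitude_mm=0.0))


@pytest.fixture(scope="session")
def sphere_masks_64():
    """Concentric sphere masks on a 64^3 unit grid, center (32,32,32)."""
    g = Grid((64, 64, 64))
    pts = g.coordinate_grid()
    c = np.full(3, 32.0)
    r = np.linalg.norm(pts - c, axis=-1)

    def ball(radius, center=None):
        if center is None:
            rr = r
        else:
            rr = np.linalg.norm(pts - np.asarray(center), axis=-1)
        return LabelMask(rr <= radius, g)

    return {"grid": g, "center": c, "r": r, "ball": ball}
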