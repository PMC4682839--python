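"""Shared fixtures.

The flow solves are the expensive pieces, so they are session-scoped and
shared between the solver unit tests, the pathline tests and the
acceptance suite.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from thrombotrace.flow import (
    ChannelGeometry,
    compute_shear_field,
    solve_steady_flow,
)
from thrombotrace.phantom import (
    AcquisitionSchedule,
    acquire_zstacks,
    make_semi_ellipsoid_phantom,
)
from thrombotrace.reconstruct import build_surface_from_stack


@pytest.fixture(scope="session")
def capillary() -> ChannelGeometry:
    """The experimental 2 × 0.2 mm capillary at 1.44 ml/min, 2.8 cP."""
    return ChannelGeometry()


@pytest.fixture(scope="session")
def empty_channel_field(capillary):
    """Desk-scale empty-channel solve: 32 cells across the 200 μm height."""
    return solve_steady_flow(
        capillary, shape=(8, 64, 32), domain_length_um=400.0, tol=1e-8
    )


@pytest.fixture(scope="session")
def obstacle_case():
    """A 30 μm-tall semi-ellipsoid thrombus in a 200 μm channel subsection.

    The channel width is a 240 μm desk-scale cut of the full capillary; the
    flow rate is chosen so the nominal wall shear 6Q/(wh²) is 1800 s⁻¹.
    Returns a dict with the surface, geometry, field, shear and tracer.
    """
    ph = make_semi_ellipsoid_phantom(30, 12, 30)
    sched = AcquisitionSchedule(
        width_px=224, height_px=96, n_slices=64, n_stacks=1, guard_slices=2
    )
    surf = build_surface_from_stack(acquire_zstacks(ph, sched)[0])
    surf.mesh.apply_translation([150.0, 120.0, 0.0])
    geom = ChannelGeometry(
        width_mm=0.24, height_mm=0.2, length_mm=0.4, flow_ml_min=0.1728
    )
    field = solve_steady_flow(
        geom,
        obstacle=surf,
        shape=(48, 30, 24),
        domain_length_um=400.0,
        tol=1e-8,
        max_steps=30000,
    )
    shear = compute_shear_field(field)
    return {
        "surface": surf,
        "geom": geom,
        "field": field,
        "shear": shear,
        "tracer": field.tracer_field(shear),
    }


def hemisphere_masks(radius_um=15.0, pixel_size_um=0.31, dz_um=0.5, pad_um=3.0):
    """Analytic binary slices of a wall-attached hemisphere (test oracle)."""
    half = radius_um + pad_um
    n = int(math.ceil(2 * half / pixel_size_um))
    x = (np.arange(n) + 0.5) * pixel_size_um - n * pixel_size_um / 2.0
    X, Y = np.meshgrid(x, x)
    zs = np.arange(0.0, radius_um + 2 * dz_um, dz_um)
    masks = []
    for z in zs:
        r2 = radius_um**2 - z**2
        masks.append((X**2 + Y**2 <= r2) if r2 > 0 else np.zeros_like(X, bool))
    return masks, zs, pixel_size_um
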