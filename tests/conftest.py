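"""Shared fixtures: one camera, and the session-scoped simulation runs that
several evaluation tests share (flood field, Derenzo, two-sphere, central
point source, offset series).  Sizes are chosen so the whole suite stays at
desk scale; every run is seeded and deterministic."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pinholesim import (
    AcquisitionProtocol,
    default_camera,
    make_derenzo_phantom,
    make_flood_phantom,
    make_point_source,
    make_two_sphere_phantom,
    make_energy_window,
    run_simulation,
)

try:  # derandomise hypothesis where it is available
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass

WIN_113 = make_energy_window([112.95], 0.10)
WIN_FULL = make_energy_window([112.95, 208.37], 0.35)


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def flood_run(camera):
    """High-statistics flood acquisition in the 113 keV +-10% window.

    Returns (counts grid, smoothed grid for division, DetectedImage).  The
    smoothing (sigma = 1 pixel) plays the role of the paper-style long
    high-statistics flood at desk-scale primaries.
    """
    src = make_flood_phantom(80.0, 100.0)
    prot = AcquisitionProtocol(
        n_primaries=1_200_000_000,
        seed=101,
        windows=(WIN_113,),
        direction_sampling="cone",
        cone_target="aperture",
        batch_size=4_000_000,
    )
    img = run_simulation(src, camera, prot)
    counts = img.counts[WIN_113].astype(float)
    return counts, gaussian_filter(counts, 1.0), img


@pytest.fixture(scope="session")
def derenzo_run(camera):
    src = make_derenzo_phantom()
    prot = AcquisitionProtocol(
        duration_s=0.35,
        seed=102,
        windows=(WIN_FULL,),
        direction_sampling="cone",
        cone_target="aperture",
        batch_size=4_000_000,
    )
    return src, run_simulation(src, camera, prot)


@pytest.fixture(scope="session")
def two_sphere_run(camera):
    src = make_two_sphere_phantom()
    prot = AcquisitionProtocol(
        duration_s=0.08,
        seed=103,
        windows=(WIN_FULL,),
        direction_sampling="cone",
        cone_target="aperture",
        batch_size=4_000_000,
    )
    return src, run_simulation(src, camera, prot)


@pytest.fixture(scope="session")
def central_point_run(camera):
    """Full-physics central 1000 MBq point source, detector-covering cone."""
    src = make_point_source(0.0, 1000.0, 100.0)
    prot = AcquisitionProtocol(
        duration_s=0.2,
        seed=104,
        windows=(WIN_FULL,),
        direction_sampling="cone",
        cone_target="detector",
        batch_size=4_000_000,
    )
    return run_simulation(src, camera, prot)


@pytest.fixture(scope="session")
def offset_runs(camera):
    """Point sources at 0..100 mm offsets (the six-source protocol)."""
    out = []
    for off in (0.0, 20.0, 40.0, 60.0, 80.0, 100.0):
        src = make_point_source(off, 1000.0, 100.0)
        prot = AcquisitionProtocol(
            duration_s=0.012,
            seed=110 + int(off),
            windows=(WIN_FULL,),
            direction_sampling="cone",
            cone_target="aperture",
        )
        out.append((off, run_simulation(src, camera, prot)))
    return out
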