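"""Shared fixtures.

Solver-backed fixtures are session-scoped: the expensive recordings
(four-case skull scene, speckle scenes) are produced once and shared by
the unit and acceptance tests that analyze them.
"""

from __future__ import annotations

import numpy as np
import pytest

from skullwave import media, solver
from skullwave.decomposition import Scene, run_four_cases
from skullwave.media import SkullModelParams, SpeckleParams


@pytest.fixture(scope="session")
def small_map():
    """A tiny uniform soft-tissue map for cheap solver runs."""
    f0 = 1.25e6
    dx = (1540.0 / f0) / 15.0
    nz, nx = int(0.03 / dx), int(0.006 / dx)
    return media.uniform_map((nz, nx), dx, attenuation=0.0)


@pytest.fixture(scope="session")
def skull_point_caseset():
    """Four-case decomposition of a seeded synthetic-skull point target.

    The scaled scene (48 mm deep, 26 mm wide, 12 grid points per
    wavelength at 1.25 MHz) used by the clutter-subtraction and
    region-statistics checks.
    """
    scene = Scene(depth=48e-3, width=26e-3, f0=1.25e6, ppw=12,
                  skull=SkullModelParams(seed=3),
                  targets=((40e-3, 0.0, 1.0),), focus=(0.0, 40e-3), seed=3)
    return run_four_cases(scene)


@pytest.fixture(scope="session")
def homogeneous_point_psf():
    """Focused point-target recording in a homogeneous medium.

    Used for PSF geometry checks (peak position, width against the
    two-way diffraction limit).
    """
    from skullwave import imaging

    f0 = 1.25e6
    ppw = 12
    dx = (1540.0 / f0) / ppw
    depth, width = 0.045, 0.024
    m = media.uniform_map((int(depth / dx), int(width / dx)), dx,
                          attenuation=0.0)
    m = media.insert_point_target(m, depth=0.035, lateral=0.0)
    arr = solver.TransducerArray(n_elements=64, pitch=0.295e-3)
    pulse = solver.Pulse(f0=f0, cycles=2, amplitude=1e5)
    delays = imaging.tx_focus_delays(arr, (0.0, 0.035))
    cfg = solver.SolverConfig(points_per_wavelength=8,
                              duration=2 * 0.042 / 1540 + 10e-6)
    res = solver.run_simulation(m, arr, pulse, cfg, tx_delays=delays,
                                focus=(0.0, 0.035))
    grid = imaging.ImageGrid.regular((0.025, 0.044), (-0.008, 0.008), 2 * dx)
    return res.channel_data, arr, grid, m, pulse


@pytest.fixture(scope="session")
def speckle_scene_recordings():
    """Focused recordings of a calibrated speckle medium at 2.5 MHz.

    Returns a dict with transmits at several lateral foci through plain
    speckle (homogeneous), one through speckle with an anechoic lesion,
    and one transcranial — the inputs of the coherence analyses.
    """
    from dataclasses import replace

    from skullwave.decomposition import _run_case
    from skullwave.media import LesionSpec

    base = Scene(depth=42e-3, width=24e-3, f0=2.5e6, ppw=8, cfl=0.55,
                 skull=None, speckle=SpeckleParams(seed=5), seed=5)
    cache: dict = {}
    homog = {}
    for fx in (-4e-3, -2e-3, 0.0, 2e-3, 4e-3):
        sc = replace(base, focus=(fx, 30e-3))
        homog[fx] = _run_case(sc, sc.case_map("homogeneous"), cache)
    lesion_scene = replace(base, lesion=LesionSpec(center=(0.0, 30e-3)),
                           focus=(0.0, 30e-3))
    lesion_cd = _run_case(lesion_scene, lesion_scene.case_map("homogeneous"), {})
    trans_scene = replace(base, skull=SkullModelParams(seed=7),
                          focus=(0.0, 30e-3))
    trans_cd = _run_case(trans_scene, trans_scene.case_map("transcranial"), {})
    return dict(array=base.array, homogeneous=homog, lesion=lesion_cd,
                transcranial=trans_cd)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
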