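"""Shared fixtures: membrane equilibria, small solved fields, cached scenes.

Everything is generated programmatically and deterministically; expensive
artefacts (field solves, membrane threshold densities) are session-scoped
so the percept and selectivity tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import retistim as rs
from retistim import fieldsolver, fixtures, membrane


@pytest.fixture(scope="session")
def params() -> membrane.ChannelParams:
    return rs.load_default_params()


@pytest.fixture(scope="session")
def rest(params) -> membrane.MembraneState:
    return membrane.resting_state(params)


@pytest.fixture(scope="session")
def jstar_biphasic(params) -> float:
    """Membrane threshold density for the clinical biphasic pulse (94 µs)."""
    return membrane.threshold_density(params, rs.biphasic_rectangular(1.0, 94e-6, 100.0))


@pytest.fixture(scope="session")
def jstar_linear(params) -> float:
    """Membrane threshold density for the 100 µs linear-decrease pulse."""
    return membrane.threshold_density(params, rs.linear_decrease(1.0, 100e-6))


@pytest.fixture(scope="session")
def lce_scene():
    scene = fixtures.make_lce_scene()
    scene.solve()
    return scene


@pytest.fixture(scope="session")
def lce_threshold(lce_scene, params, rest):
    """(jc_unit, threshold amplitude) of the 3D-carrier scene at 0.1 nA steps."""
    sol = lce_scene.solve()
    jc_unit = fieldsolver.surface_current_density(sol, lce_scene.cell)
    thr = membrane.threshold_search(
        params, jc_unit, lce_scene.waveform, i_start=0.1e-9, di=0.1e-9, rest=rest,
    )
    return jc_unit, thr


@pytest.fixture(scope="session")
def hex_scene_cache():
    """Solved hexagonal-array scenes keyed by (proximity, theta, reduced, amplitude)."""
    cache: dict = {}

    def get(proximity=10.0, theta=0.0, reduced=False, amplitude=13e-6,
            pair=(11, 12)):
        key = (proximity, theta, reduced, amplitude, pair)
        if key not in cache:
            scene = fixtures.make_hex_scene(
                pairs=[pair], proximity=proximity, theta=theta,
                amplitude=amplitude, reduced_conductivity=reduced,
            )
            # reuse the unit field of an identical geometry solved at a
            # different amplitude (the field problem is amplitude-independent)
            for (p2, t2, r2, _a2, pr2), other in list(cache.items()):
                if (p2, t2, r2, pr2) == (proximity, theta, reduced, pair):
                    scene._solutions = other._solutions
                    break
            scene.solve_pair(pair)
            cache[key] = scene
        return cache[key]

    return get


@pytest.fixture(scope="session")
def small_two_electrode_field():
    """Homogeneous small grid with two symmetric disc electrodes, solved.

    Cheap stand-in for a full scene: used for linearity, reciprocity,
    power-balance and activation-coupling tests.
    """
    h = 5.0
    n = 41
    nz = 25
    sigma = np.full((n, n, nz), 0.5)
    active = np.zeros_like(sigma, dtype=bool)
    ground = np.zeros_like(sigma, dtype=bool)
    # discs of radius 2 voxels at z index 18, centred at x = ±8 voxels
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    for mask, cx in ((active, 12), (ground, 28)):
        disc = (xx - cx) ** 2 + (yy - 20) ** 2 <= 4
        mask[disc.T, 18] = True
    grid = fieldsolver.ConductivityGrid(
        h=h, origin=(-100.0, -100.0, -90.0), sigma=sigma,
        active_mask=active, ground_mask=ground,
    )
    return fieldsolver.solve_unit_field(grid)
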