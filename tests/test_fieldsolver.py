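"""Volume-conduction solver verification against closed-form oracles."""

import numpy as np
import pytest

from retistim import fixtures
from retistim.fieldsolver import (
    BoundaryDrive,
    ConductivityGrid,
    SolverError,
    electrode_surface_current_density,
    solve_unit_field,
    sphere_points,
    suprathreshold_volume,
    surface_current_density,
)
from retistim.waveforms import linear_decrease


@pytest.fixture(scope="module")
def monopole_solution():
    """Unit source in a homogeneous box with manufactured (analytic) boundary.

    Dirichlet values on the outer boundary are taken from the monopole
    closed form, so the interior solve must reproduce I/(4πσr) up to
    discretization error.
    """
    h, n = 4.0, 33
    sigma_v = 1.5
    half = h * (n - 1) / 2.0
    origin = (-half, -half, -half)
    sigma = np.full((n, n, n), sigma_v)
    active = np.zeros_like(sigma, dtype=bool)
    active[n // 2, n // 2, n // 2] = True
    ground = np.zeros_like(active)
    field = fixtures.make_analytic_field("monopole", sigma=sigma_v, current=1.0)
    ax = origin[0] + h * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vals = field.potential(pts).reshape(sigma.shape)
    dirichlet = np.full(sigma.shape, np.nan)
    for sl in (np.s_[0, :, :], np.s_[-1, :, :], np.s_[:, 0, :], np.s_[:, -1, :],
               np.s_[:, :, 0], np.s_[:, :, -1]):
        dirichlet[sl] = vals[sl]
    grid = ConductivityGrid(h=h, origin=origin, sigma=sigma, active_mask=active,
                            ground_mask=ground, dirichlet=dirichlet)
    return solve_unit_field(grid), field


class TestMonopoleOracle:
    def test_potential_matches_closed_form_beyond_10h(self, monopole_solution):
        sol, field = monopole_solution
        rng = np.random.default_rng(7)
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for r in (40.0, 48.0, 56.0):
            pts = dirs * r
            v_num = sol.potential_at(pts)
            v_ref = field.potential(pts)
            err = np.abs(v_num - v_ref) / np.abs(v_ref)
            assert err.max() < 0.02

    def test_closed_form_value_at_100um(self):
        field = fixtures.make_analytic_field("monopole", sigma=1.5, current=1e-6)
        v = field.potential(np.array([[100.0, 0.0, 0.0]]))[0]
        assert v == pytest.approx(0.5305e-3, rel=1e-3)

    def test_flux_through_enclosing_sphere_equals_injected_current(self, monopole_solution):
        sol, _ = monopole_solution
        normals = sphere_points(512)
        for r in (30.0, 44.0):
            pts = r * normals
            J = sol.current_density_at(pts)
            flux = np.einsum("ij,ij->i", J, normals).mean() * 4 * np.pi * (r * 1e-6) ** 2
            assert flux == pytest.approx(1.0, rel=0.03)

    def test_error_decreases_with_grid_refinement(self):
        errs = []
        for h, n in ((8.0, 17), (4.0, 33)):
            sigma_v = 1.5
            half = h * (n - 1) / 2.0
            sigma = np.full((n, n, n), sigma_v)
            active = np.zeros_like(sigma, dtype=bool)
            active[n // 2, n // 2, n // 2] = True
            field = fixtures.make_analytic_field("monopole", sigma=sigma_v, current=1.0)
            ax = -half + h * np.arange(n)
            X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
            vals = field.potential(
                np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])).reshape(sigma.shape)
            dirichlet = np.full(sigma.shape, np.nan)
            for sl in (np.s_[0, :, :], np.s_[-1, :, :], np.s_[:, 0, :],
                       np.s_[:, -1, :], np.s_[:, :, 0], np.s_[:, :, -1]):
                dirichlet[sl] = vals[sl]
            grid = ConductivityGrid(h=h, origin=(-half, -half, -half), sigma=sigma,
                                    active_mask=active, ground_mask=np.zeros_like(active),
                                    dirichlet=dirichlet)
            sol = solve_unit_field(grid)
            pts = np.array([[48.0, 16.0, 8.0], [0.0, 56.0, 0.0], [-40.0, -24.0, 16.0]])
            errs.append(np.max(np.abs(sol.potential_at(pts) - field.potential(pts))
                               / np.abs(field.potential(pts))))
        assert errs[1] < errs[0]


class TestSolverStructure:
    def test_reciprocity_swapping_electrodes(self, small_two_electrode_field):
        """Swapping source and sink negates the potential (source formulation),
        and the two-terminal access resistance is direction-independent."""
        g = small_two_electrode_field.grid
        fwd = solve_unit_field(
            ConductivityGrid(h=g.h, origin=g.origin, sigma=g.sigma,
                             active_mask=g.active_mask, ground_mask=g.ground_mask),
            ground_mode="source")
        rev = solve_unit_field(
            ConductivityGrid(h=g.h, origin=g.origin, sigma=g.sigma,
                             active_mask=g.ground_mask, ground_mask=g.active_mask),
            ground_mode="source")
        scale = np.nanmax(np.abs(fwd.V))
        assert np.nanmax(np.abs(fwd.V + rev.V)) < 1e-5 * scale
        # default (grounded-electrode) formulation: R_access symmetric
        sol2 = solve_unit_field(
            ConductivityGrid(h=g.h, origin=g.origin, sigma=g.sigma,
                             active_mask=g.ground_mask, ground_mask=g.active_mask))
        assert sol2.access_resistance == pytest.approx(
            small_two_electrode_field.access_resistance, rel=0.02)

    def test_boundary_drive_is_linear_in_amplitude(self, small_two_electrode_field):
        sol = small_two_electrode_field
        from retistim.geometry import CellPlacement

        cell = CellPlacement(base_center=(0.0, 0.0, -30.0), diameter=10.0,
                             base_proximity=0.0)
        jc = surface_current_density(sol, cell)
        t = np.linspace(0, 100e-6, 11)
        d1 = BoundaryDrive(jc, linear_decrease(1e-9, 100e-6))
        d2 = BoundaryDrive(jc, linear_decrease(2e-9, 100e-6))
        np.testing.assert_allclose(d2.series(t), 2 * d1.series(t))
        assert d2.peak == pytest.approx(2 * d1.peak)

    def test_zero_waveform_drive_is_identically_zero(self, small_two_electrode_field):
        from retistim.geometry import CellPlacement

        cell = CellPlacement(base_center=(0.0, 0.0, -30.0), diameter=10.0,
                             base_proximity=0.0)
        jc = surface_current_density(small_two_electrode_field, cell)
        d = BoundaryDrive(jc, linear_decrease(0.0, 100e-6))
        assert d.peak == 0.0
        assert np.all(d.series(np.linspace(0, 2e-4, 7)) == 0.0)

    def test_normal_current_continuous_across_conductivity_jump(self):
        """Uniform axial current through a two-layer slab refracts correctly."""
        n, nz, h = 9, 40, 5.0
        sigma = np.full((n, n, nz), 1.0)
        sigma[:, :, : nz // 2] = 0.1
        active = np.zeros_like(sigma, dtype=bool)
        ground = np.zeros_like(active)
        active[:, :, -1] = True
        ground[:, :, 0] = True
        grid = ConductivityGrid(h=h, origin=(0, 0, 0), sigma=sigma,
                                active_mask=active, ground_mask=ground)
        sol = solve_unit_field(grid)
        jz = sol.J[n // 2, n // 2, :, 2]
        k = nz // 2
        # J_z continuous at the interface …
        assert jz[k - 2] == pytest.approx(jz[k + 1], rel=0.02)
        # … while E = J/σ jumps by the conductivity ratio
        v = sol.V[n // 2, n // 2, :]
        e_low = (v[k - 3] - v[k - 2]) / h
        e_high = (v[k + 2] - v[k + 3]) / h
        assert e_low / e_high == pytest.approx(1.0 / 0.1, rel=0.05)

    def test_disconnected_electrodes_raise(self):
        sigma = np.full((9, 9, 9), 1.0)
        sigma[:, :, 4] = 0.0  # insulating wall between the electrodes
        active = np.zeros_like(sigma, dtype=bool)
        ground = np.zeros_like(active)
        active[4, 4, 8] = True
        ground[4, 4, 0] = True
        grid = ConductivityGrid(h=5.0, origin=(0, 0, 0), sigma=sigma,
                                active_mask=active, ground_mask=ground)
        with pytest.raises(SolverError):
            solve_unit_field(grid, maxiter=400)


class TestDerivedQuantities:
    def test_electrode_surface_current_density_examples(self):
        assert electrode_surface_current_density(0.5e-9, 7.5) == pytest.approx(11.32, abs=0.01)
        assert electrode_surface_current_density(13e-6, 100.0) == pytest.approx(1655, rel=1e-3)
        assert electrode_surface_current_density(0.0, 7.5) == 0.0

    def test_suprathreshold_volume_limits(self, monopole_solution):
        sol, _ = monopole_solution
        assert suprathreshold_volume(sol, 1.0, 1e30) == 0.0
        nearly_all = suprathreshold_volume(sol, 1.0, 1e-30)
        total = sol.grid.h ** 3 * sol.grid.sigma.size
        assert nearly_all == pytest.approx(total, rel=0.01)

    def test_suprathreshold_volume_matches_analytic_level_set(self, monopole_solution):
        """|J| = I/(4πr²) super-level sets are spheres of known volume."""
        sol, _ = monopole_solution
        h = sol.grid.h
        for r_star in (30.0, 40.0):
            j_thr = 1.0 / (4 * np.pi * (r_star * 1e-6) ** 2)
            vol = suprathreshold_volume(sol, 1.0, j_thr)
            exact = 4.0 / 3.0 * np.pi * r_star ** 3
            shell = 4.0 * np.pi * r_star ** 2 * h  # one-voxel-shell bound
            assert abs(vol - exact) < shell

    def test_sphere_covering_is_deterministic_and_uniform(self):
        p1 = sphere_points(128)
        p2 = sphere_points(128)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(np.linalg.norm(p1, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(p1.mean(axis=0)) < 0.02
        with pytest.raises(ValueError):
            sphere_points(50)
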