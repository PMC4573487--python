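"""Reaction-diffusion fields: rasterization, FTCS stepping, and oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_bvp
from scipy.special import k0

from socolony.fields import (
    ChemicalField,
    ChemicalParams,
    DensityField,
    rasterize_density,
    sample_at,
    stable_dt,
    step_chemical,
    step_nutrient,
)
from socolony.mechanics import Species

from conftest import make_cell


class TestRasterizeDensity:
    def test_no_cells_gives_zeros(self):
        field = rasterize_density([], shape=(4, 4), spacing=5.0)
        assert np.all(field.grid == 0)

    def test_single_cell_area_ratio(self):
        # rod length chosen so the footprint is exactly 2 um^2
        rod = (2.0 - math.pi / 4.0) / 1.0
        cell = make_cell(x=12.5, y=12.5, rod=rod)
        field = rasterize_density([cell], shape=(5, 5), spacing=5.0, origin=(0, 0))
        assert field.grid[2, 2] == pytest.approx(2.0 / 25.0)
        assert field.grid.sum() == pytest.approx(2.0 / 25.0)

    def test_total_area_is_conserved(self, rng):
        cells = [
            make_cell(i, x=rng.uniform(20, 80), y=rng.uniform(20, 80),
                      angle=rng.uniform(0, 2 * math.pi), rod=rng.uniform(0, 3))
            for i in range(100)
        ]
        field = rasterize_density(cells, shape=(20, 20), spacing=5.0, origin=(0, 0))
        total = sum(c.area for c in cells)
        assert field.grid.sum() * 25.0 == pytest.approx(total, rel=1e-2)

    def test_species_filter_restricts_to_producers(self):
        g = make_cell(0, x=5, y=5, species=Species.GREEN)
        r = make_cell(1, x=15, y=15, species=Species.RED)
        field = rasterize_density([g, r], (4, 4), 5.0, (0, 0), species_filter=Species.RED)
        assert field.grid[1, 1] == 0
        assert field.grid[3, 3] > 0

    def test_cell_outside_grid_names_the_cell(self):
        cell = make_cell(cid=42, x=100.0, y=0.0)
        with pytest.raises(ValueError, match="42"):
            rasterize_density([cell], shape=(4, 4), spacing=5.0, origin=(0, 0))


def _uniform_density(value, shape, spacing=5.0):
    return DensityField(np.full(shape, float(value)), spacing, np.zeros(2))


def _iterate_to_steady(field, rho, params, dt, stepper, tol=1e-12, max_steps=400_000):
    for _ in range(max_steps):
        new = stepper(field, rho, params, dt)
        if np.abs(new.grid - field.grid).max() < tol:
            return new
        field = new
    raise AssertionError("field failed to reach steady state")


class TestStepNutrient:
    def test_uniform_saturated_state_is_steady(self):
        field = ChemicalField(np.ones((8, 8)), boundary="dirichlet_one")
        out = step_nutrient(field, _uniform_density(0.0, (8, 8)), ChemicalParams.nutrient_defaults(), 1e-4)
        np.testing.assert_allclose(out.grid, 1.0)

    def test_pointwise_uptake_in_reaction_limit(self):
        # D = 0, kappa >> n: dn ~= -alpha*rho*n/kappa * dt
        params = ChemicalParams(D=0.0, alpha_n=2.0, kappa=100.0, beta=0.0)
        grid = np.full((6, 6), 0.5)
        field = ChemicalField(grid.copy(), boundary="neumann")
        dt = 1e-3
        out = step_nutrient(field, _uniform_density(0.8, (6, 6)), params, dt)
        expected = 0.5 - 2.0 * 0.8 * 0.5 / (100.0 + 0.5) * dt
        np.testing.assert_allclose(out.grid[1:-1, 1:-1], expected, rtol=1e-12)

    def test_stability_violation_reports_admissible_dt(self):
        field = ChemicalField(np.ones((8, 8)))
        params = ChemicalParams.nutrient_defaults()
        with pytest.raises(ValueError, match="admissible"):
            step_nutrient(field, _uniform_density(1.0, (8, 8)), params, dt=1.0)

    def test_maximum_principle_bounds_nutrient(self, rng):
        shape = (12, 12)
        params = ChemicalParams(D=200.0, alpha_n=30.0, kappa=0.3)
        rho = DensityField(rng.uniform(0, 1.5, shape), 5.0, np.zeros(2))
        field = ChemicalField(rng.uniform(0, 1, shape))
        dt = 0.9 * stable_dt(params.D, 5.0, params.alpha_n * 1.5 / params.kappa)
        for _ in range(300):
            field = step_nutrient(field, rho, params, dt)
            assert field.grid.min() >= 0.0
            assert field.grid.max() <= 1.0 + 1e-12

    def test_relaxes_to_one_without_cells(self, rng):
        params = ChemicalParams(D=500.0, alpha_n=10.0, kappa=0.3)
        field = ChemicalField(rng.uniform(0, 1, (10, 10)))
        dt = 0.9 * stable_dt(params.D, 5.0, 0.0)
        for _ in range(3000):
            field = step_nutrient(field, _uniform_density(0.0, (10, 10)), params, dt)
        np.testing.assert_allclose(field.grid, 1.0, atol=1e-6)

    def test_slab_steady_state_matches_boundary_value_oracle(self):
        """Iterated FTCS steps on a 1-D slab converge to the solve_bvp
        solution of D n'' = alpha rho n/(kappa+n) with n = 1 at both walls."""
        spacing = 2.5
        nx = 81  # slab x extent 202.5 um
        params = ChemicalParams(D=3.0e4, alpha_n=60.0, kappa=0.3)
        rho = _uniform_density(1.0, (nx, 6), spacing)
        field = ChemicalField(np.ones((nx, 6)), spacing, np.zeros(2), boundary="slab_x")
        dt = 0.9 * stable_dt(params.D, spacing, params.alpha_n / params.kappa)
        field = _iterate_to_steady(field, rho, params, dt, step_nutrient)
        profile = field.grid[:, 3]
        # independent oracle on the same domain (lattice-center endpoints)
        xa, xb = 0.5 * spacing, (nx - 0.5) * spacing
        xs = (np.arange(nx) + 0.5) * spacing

        def ode(x, y):
            return np.vstack([y[1], params.alpha_n * y[0] / (params.D * (params.kappa + y[0]))])

        def bc(ya, yb):
            return np.array([ya[0] - 1.0, yb[0] - 1.0])

        mesh = np.linspace(xa, xb, 201)
        guess = np.vstack([np.full(mesh.size, 0.5), np.zeros(mesh.size)])
        sol = solve_bvp(ode, bc, mesh, guess, tol=1e-8, max_nodes=20000)
        assert sol.success
        oracle = sol.sol(xs)[0]
        assert np.max(np.abs(profile - oracle)) / oracle.max() < 0.01


class TestStepChemical:
    def test_reactionless_fixed_point(self):
        # D = 0: c -> rho/beta pointwise in the interior
        params = ChemicalParams(D=0.0, beta=2.0)
        field = ChemicalField(np.zeros((6, 6)), boundary="reactive")
        rho = _uniform_density(0.5, (6, 6))
        dt = 0.4 * stable_dt(0.0, 5.0, params.beta)
        for _ in range(3000):
            field = step_chemical(field, rho, params, dt)
        np.testing.assert_allclose(field.grid[1:-1, 1:-1], 0.25, atol=1e-6)
        np.testing.assert_allclose(field.grid[0, :], 0.0)

    def test_mass_decays_exponentially_without_production(self):
        params = ChemicalParams(D=50.0, beta=3.0)
        field = ChemicalField(np.full((10, 10), 0.7), boundary="neumann")
        rho = _uniform_density(0.0, (10, 10))
        dt = 1e-3  # keep beta*dt small so forward Euler tracks the exponential
        steps = 400
        for _ in range(steps):
            field = step_chemical(field, rho, params, dt)
        expected = 0.7 * math.exp(-params.beta * steps * dt)
        np.testing.assert_allclose(field.grid.mean(), expected, rtol=5e-3)

    def test_point_source_profile_matches_screened_poisson_oracle(self):
        """The steady radial profile of a point source decays like the
        modified Bessel function K0(r/lambda), lambda = sqrt(D/beta)."""
        spacing = 2.0
        n = 101
        params = ChemicalParams(D=100.0, beta=1.0)  # lambda = 10 um
        rho = np.zeros((n, n))
        c0 = n // 2
        rho[c0, c0] = 1.0
        rho = DensityField(rho, spacing, np.zeros(2))
        field = ChemicalField(np.zeros((n, n)), spacing, np.zeros(2), boundary="reactive")
        dt = 0.9 * stable_dt(params.D, spacing, params.beta)
        for _ in range(1200):
            field = step_chemical(field, rho, params, dt)
        lam = math.sqrt(params.D / params.beta)
        radii = np.array([6.0, 10.0, 16.0, 20.0, 26.0, 30.0])
        vals = np.array([field.grid[c0 + int(r / spacing), c0] for r in radii])
        oracle = k0(radii / lam)
        ratio = vals / oracle
        # profile shape: relative deviation from the analytic decay < 5 %
        assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 0.05

    def test_bounded_by_production_over_degradation(self, rng):
        params = ChemicalParams(D=80.0, beta=2.0)
        rho = DensityField(rng.uniform(0, 1.6, (10, 10)), 5.0, np.zeros(2))
        field = ChemicalField(np.zeros((10, 10)), boundary="reactive")
        dt = 0.5 * stable_dt(params.D, 5.0, params.beta)
        bound = rho.grid.max() / params.beta
        for _ in range(500):
            field = step_chemical(field, rho, params, dt)
            assert field.grid.min() >= 0.0
            assert field.grid.max() <= bound + 1e-9


class TestSampleAt:
    def test_uniform_field_everywhere(self):
        field = ChemicalField(np.full((6, 6), 0.37), 5.0, np.zeros(2))
        assert sample_at(field, (1.0, 29.0)) == pytest.approx(0.37)

    def test_linear_ramp_exact_at_cell_centers(self):
        grid = np.tile(np.arange(8.0)[:, None], (1, 8))
        field = ChemicalField(grid, 5.0, np.zeros(2))
        for i in range(8):
            assert sample_at(field, ((i + 0.5) * 5.0, 17.0)) == pytest.approx(float(i))

    def test_agrees_with_direct_indexing(self, rng):
        grid = rng.uniform(size=(12, 9))
        field = ChemicalField(grid, 5.0, np.array([-10.0, 3.0]))
        for _ in range(100):
            pos = np.array([rng.uniform(-10, 50), rng.uniform(3, 48)])
            ix, iy = ((pos - field.origin) // 5.0).astype(int)
            assert sample_at(field, pos) == grid[ix, iy]

    def test_outside_grid_raises(self):
        field = ChemicalField(np.ones((4, 4)), 5.0, np.zeros(2))
        with pytest.raises(ValueError, match="outside"):
            sample_at(field, (25.0, 0.0))


def test_grid_convergence_of_slab_steady_state():
    """Doubling the lattice resolution changes the steady slab profile < 2%."""
    params = ChemicalParams(D=3.0e4, alpha_n=60.0, kappa=0.3)
    profiles = {}
    for spacing, nx in ((5.0, 41), (2.5, 81)):
        rho = _uniform_density(1.0, (nx, 6), spacing)
        field = ChemicalField(np.ones((nx, 6)), spacing, np.zeros(2), boundary="slab_x")
        dt = 0.9 * stable_dt(params.D, spacing, params.alpha_n / params.kappa)
        field = _iterate_to_steady(field, rho, params, dt, step_nutrient)
        # measure distance from the Dirichlet wall (the ring-cell center),
        # which is where both discretizations pin n = 1
        xs = np.arange(nx) * spacing
        profiles[spacing] = (xs, field.grid[:, 3])
    xs_c, coarse = profiles[5.0]
    xs_f, fine = profiles[2.5]
    half = xs_c <= 100.0  # compare the near-wall half; the far wall differs
    interp = np.interp(xs_c[half], xs_f, fine)
    assert np.max(np.abs(coarse[half] - interp)) / interp.max() < 0.02
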