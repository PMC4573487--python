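"""Reaction-diffusion lattices for nutrient and secreted chemicals.

Nutrient obeys dn/dt = D_n lap(n) - alpha_n * rho * n/(kappa + n) with the
domain boundary held at the external-source value 1 (all concentrations are
scaled to it), so 0 <= n <= 1 by the maximum principle.  Secreted chemicals
obey dc/dt = D_c lap(c) + rho_c - beta_c * c with an absorbing boundary
(c = 0 on the ring) standing in for flow out of the open system; production
is constitutive and proportional to the producer cell density, with c scaled
so the production term carries no prefactor.  sqrt(D_c/beta_c) sets the
interaction length scale.

Fields are explicit FTCS-stepped on a square lattice.  The density a field
consumes is the summed cell footprint area per lattice cell divided by the
lattice cell area, apportioned by sample points along each cell's axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._kernels import deposit_axis_samples
from .mechanics import Cell

__all__ = [
    "ChemicalParams",
    "ChemicalField",
    "DensityField",
    "rasterize_density",
    "step_nutrient",
    "step_chemical",
    "sample_at",
    "stable_dt",
]

#: Default lattice spacing (um); shared with the colony metrics grid.
DEFAULT_SPACING = 5.0


@dataclass
class ChemicalParams:
    """Kinetic parameters of one chemical field.

    D in um^2/tau (tau = 30 min).  For nutrient, alpha_n (consumption rate,
    1/tau) and kappa (half-saturation) apply; for produced chemicals, beta
    (degradation rate, 1/tau) applies.  Defaults give a nutrient penetration
    depth of a few tens of um into a packed colony and an interaction length
    sqrt(D/beta) = 10 um, a few cell lengths.
    """

    D: float = 100.0
    alpha_n: float = 10.0
    kappa: float = 0.3
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.D < 0 or self.alpha_n < 0 or self.beta < 0:
            raise ValueError("rates must be >= 0")

    @classmethod
    def nutrient_defaults(cls) -> "ChemicalParams":
        return cls(D=3.0e4, alpha_n=10.0, kappa=0.3, beta=0.0)

    @classmethod
    def chemical_defaults(cls) -> "ChemicalParams":
        return cls(D=100.0, alpha_n=0.0, beta=1.0)


@dataclass
class ChemicalField:
    """A 2-D concentration lattice.

    grid[ix, iy] is the concentration of the lattice cell whose lower-left
    corner is origin + (ix, iy)*spacing.  boundary is one of 'dirichlet_one'
    (ring held at 1; nutrient), 'reactive' (absorbing ring, c = 0; secreted
    chemicals) or 'neumann' (no-flux; used for closed-box checks).
    """

    grid: np.ndarray
    spacing: float = DEFAULT_SPACING
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))
    boundary: str = "dirichlet_one"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.boundary not in ("dirichlet_one", "reactive", "neumann", "slab_x"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    def copy(self) -> "ChemicalField":
        return ChemicalField(self.grid.copy(), self.spacing, self.origin.copy(), self.boundary)


@dataclass
class DensityField:
    """Dimensionless cell-area density per lattice cell (area / lattice area)."""

    grid: np.ndarray
    spacing: float = DEFAULT_SPACING
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))


def rasterize_density(
    cells: list[Cell],
    shape: tuple[int, int],
    spacing: float = DEFAULT_SPACING,
    origin=(0.0, 0.0),
    species_filter=None,
    samples: int = 9,
) -> DensityField:
    """Cell-area density on a lattice.

    Each cell's footprint area is split over ``samples`` points along its
    axis and deposited into the containing lattice cells, then normalized by
    the lattice cell area.  ``species_filter`` restricts to one species
    (producer density).  Raises if any cell lies outside the grid.
    """
    sel = [c for c in cells if species_filter is None or c.species == species_filter]
    grid = np.zeros(shape)
    if sel:
        x = np.array([c.center[0] for c in sel])
        y = np.array([c.center[1] for c in sel])
        ca = np.cos([c.angle for c in sel])
        sa = np.sin([c.angle for c in sel])
        rod = np.array([c.rod_length for c in sel])
        area = np.array([c.area for c in sel])
        misses = deposit_axis_samples(
            x, y, ca, sa, rod, area, float(origin[0]), float(origin[1]),
            1.0 / spacing, shape[0], shape[1], samples, grid,
        )
        if misses:
            for c in sel:
                lo = np.asarray(origin)
                hi = lo + np.array(shape) * spacing
                ends = c.endpoints
                for p in (*ends, c.center):
                    if np.any(p < lo) or np.any(p >= hi):
                        raise ValueError(f"cell {c.id} lies outside the density grid")
            raise ValueError("cell sample outside the density grid")
    grid /= spacing * spacing
    return DensityField(grid, spacing, np.asarray(origin, dtype=float))


def stable_dt(D: float, spacing: float, rate: float = 0.0) -> float:
    """Largest admissible FTCS timestep for diffusion D plus local rate."""
    return spacing**2 / (4.0 * D + spacing**2 * rate + 1e-300)


def _laplacian(g: np.ndarray, spacing: float) -> np.ndarray:
    out = np.zeros_like(g)
    out[1:-1, 1:-1] = (
        g[2:, 1:-1] + g[:-2, 1:-1] + g[1:-1, 2:] + g[1:-1, :-2] - 4.0 * g[1:-1, 1:-1]
    ) / (spacing * spacing)
    return out


def _apply_boundary(grid: np.ndarray, boundary: str, value: float) -> None:
    if boundary == "neumann":
        grid[0, :] = grid[1, :]
        grid[-1, :] = grid[-2, :]
        grid[:, 0] = grid[:, 1]
        grid[:, -1] = grid[:, -2]
    elif boundary == "slab_x":
        # fixed value on the x edges, no-flux on the y edges: a 1-D slab
        grid[:, 0] = grid[:, 1]
        grid[:, -1] = grid[:, -2]
        grid[0, :] = value
        grid[-1, :] = value
    else:
        grid[0, :] = value
        grid[-1, :] = value
        grid[:, 0] = value
        grid[:, -1] = value


def nutrient_step_inplace(
    grid: np.ndarray, rho: np.ndarray, params: ChemicalParams, dt: float,
    spacing: float, boundary: str = "dirichlet_one",
) -> None:
    """One FTCS step of the nutrient equation, operating on the raw array."""
    lap = _laplacian(grid, spacing)
    uptake = params.alpha_n * rho * grid / (params.kappa + grid)
    grid[1:-1, 1:-1] += dt * (params.D * lap[1:-1, 1:-1] - uptake[1:-1, 1:-1])
    _apply_boundary(grid, boundary, 1.0)
    np.clip(grid, 0.0, None, out=grid)


def chemical_step_inplace(
    grid: np.ndarray, rho_prod: np.ndarray, params: ChemicalParams, dt: float,
    spacing: float, boundary: str = "reactive",
) -> None:
    """One FTCS step of a produced chemical, operating on the raw array."""
    lap = _laplacian(grid, spacing)
    grid[1:-1, 1:-1] += dt * (
        params.D * lap[1:-1, 1:-1] + rho_prod[1:-1, 1:-1] - params.beta * grid[1:-1, 1:-1]
    )
    _apply_boundary(grid, boundary, 0.0)
    np.clip(grid, 0.0, None, out=grid)


def _check_dt(dt: float, params: ChemicalParams, spacing: float, rate: float) -> None:
    admissible = stable_dt(params.D, spacing, rate)
    if dt > admissible * (1.0 + 1e-12):
        raise ValueError(
            f"timestep {dt:g} violates the FTCS stability bound; "
            f"admissible dt <= {admissible:g}"
        )


def step_nutrient(
    field: ChemicalField, rho: DensityField, params: ChemicalParams, dt: float
) -> ChemicalField:
    """One explicit step of dn/dt = D lap(n) - alpha_n*rho*n/(kappa+n)."""
    if field.grid.shape != rho.grid.shape:
        raise ValueError("field and density grids must share a shape")
    rate = params.alpha_n * float(rho.grid.max(initial=0.0)) / params.kappa
    _check_dt(dt, params, field.spacing, rate)
    out = field.copy()
    nutrient_step_inplace(out.grid, rho.grid, params, dt, field.spacing, field.boundary)
    return out


def step_chemical(
    field: ChemicalField, rho_producers: DensityField, params: ChemicalParams, dt: float
) -> ChemicalField:
    """One explicit step of dc/dt = D lap(c) + rho_c - beta*c."""
    if field.grid.shape != rho_producers.grid.shape:
        raise ValueError("field and density grids must share a shape")
    _check_dt(dt, params, field.spacing, params.beta)
    out = field.copy()
    chemical_step_inplace(
        out.grid, rho_producers.grid, params, dt, field.spacing, field.boundary
    )
    return out


def sample_at(field: ChemicalField, position, mode: str = "nearest") -> float:
    """Concentration at a spatial position.

    'nearest' (default) returns the containing lattice cell's value;
    'bilinear' interpolates between the four surrounding cell centers.
    """
    pos = np.asarray(position, dtype=float)
    rel = (pos - field.origin) / field.spacing
    nx, ny = field.grid.shape
    if not (0.0 <= rel[0] < nx and 0.0 <= rel[1] < ny):
        raise ValueError(f"position {position} outside the field grid")
    if mode == "nearest":
        return float(field.grid[int(rel[0]), int(rel[1])])
    if mode != "bilinear":
        raise ValueError("mode must be 'nearest' or 'bilinear'")
    fx = np.clip(rel[0] - 0.5, 0.0, nx - 1.0)
    fy = np.clip(rel[1] - 0.5, 0.0, ny - 1.0)
    i0, j0 = int(fx), int(fy)
    i1, j1 = min(i0 + 1, nx - 1), min(j0 + 1, ny - 1)
    tx, ty = fx - i0, fy - j0
    g = field.grid
    return float(
        (1 - tx) * (1 - ty) * g[i0, j0]
        + tx * (1 - ty) * g[i1, j0]
        + (1 - tx) * ty * g[i0, j1]
        + tx * ty * g[i1, j1]
    )
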