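"""Colony-structure metrics: abundance, roughness, radius, lineages, sectors.

The morphology metrics work on a 5-um occupancy lattice: a lattice cell is
occupied if at least one cell sample falls in it, the colony edge is the set
of occupied lattice cells with an empty 4-neighbor, the colony center is the
area-weighted mean cell position, the radius is the mean edge distance from
the center and the roughness is the standard deviation of those distances
in units of one lattice cell.  An independent radius estimate comes from
the moment of inertia under a uniform-disc assumption, R = sqrt(2 I / A).

Diversity metrics look only at *active* cells — those whose local Monod
growth factor n/(kappa+n) is within two exponential decays (a factor e^-2)
of the current population maximum, i.e. the growing rim.  Surviving lineages
are the distinct seed ancestors among active cells; sectors are connected
same-species clusters of more than 100 active cells, counted on a smoothed
fine raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .fields import ChemicalField, DensityField, sample_at, DEFAULT_SPACING
from .growth import GrowthParams
from .mechanics import Cell, Species

__all__ = [
    "OccupancyLattice",
    "MetricsRecord",
    "green_fraction",
    "occupancy_lattice",
    "colony_edge",
    "roughness_and_radius",
    "radius_from_inertia",
    "active_cells",
    "surviving_lineages",
    "count_sectors",
    "density_profile",
    "compute_metrics",
]


@dataclass
class OccupancyLattice:
    """Boolean occupancy on a square lattice (grid[ix, iy])."""

    grid: np.ndarray
    spacing: float = DEFAULT_SPACING
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))


@dataclass
class MetricsRecord:
    time: float
    total_cells: int
    green_fraction: float
    roughness: float  # units of one lattice cell
    radius_edge: float  # um
    radius_inertia: float  # um
    lineages: int
    green_lineages: int
    red_lineages: int
    sectors: int | None = None


def green_fraction(cells: list[Cell]) -> float:
    """Fraction of green cells; requires at least one cell."""
    if not cells:
        raise ValueError("green_fraction needs at least one cell")
    return sum(1 for c in cells if c.species == Species.GREEN) / len(cells)


def _axis_samples(cells: list[Cell], samples: int) -> np.ndarray:
    pts = []
    for c in cells:
        fr = (np.arange(samples) + 0.5) / samples - 0.5
        pts.append(c.center[None, :] + fr[:, None] * c.rod_length * c.axis[None, :])
    return np.concatenate(pts, axis=0)


def occupancy_lattice(
    cells: list[Cell],
    spacing: float = DEFAULT_SPACING,
    origin=None,
    samples: int = 9,
    pad: int = 2,
) -> OccupancyLattice:
    """Occupancy from cell axis samples; auto-sized to the colony extent."""
    if not cells:
        raise ValueError("occupancy needs at least one cell")
    pts = _axis_samples(cells, samples)
    if origin is None:
        lo = pts.min(axis=0) - pad * spacing
        lo = np.floor(lo / spacing) * spacing
    else:
        lo = np.asarray(origin, dtype=float)
    idx = np.floor((pts - lo) / spacing).astype(int)
    if np.any(idx < 0):
        raise ValueError("cells extend below the lattice origin")
    shape = idx.max(axis=0) + 1 + pad
    grid = np.zeros(tuple(shape), dtype=bool)
    grid[idx[:, 0], idx[:, 1]] = True
    return OccupancyLattice(grid, spacing, lo)


def colony_edge(lattice: OccupancyLattice) -> np.ndarray:
    """Positions (um) of occupied lattice cells with >= 1 empty 4-neighbor."""
    g = lattice.grid
    if not g.any():
        raise ValueError("no occupied lattice cells")
    padded = np.pad(g, 1, constant_values=False)
    full = (
        padded[2:, 1:-1] & padded[:-2, 1:-1] & padded[1:-1, 2:] & padded[1:-1, :-2]
    )
    edge = g & ~full
    idx = np.argwhere(edge)
    return lattice.origin + (idx + 0.5) * lattice.spacing


def _area_weighted_center(cells: list[Cell]) -> np.ndarray:
    areas = np.array([c.area for c in cells])
    centers = np.array([c.center for c in cells])
    return (areas[:, None] * centers).sum(axis=0) / areas.sum()


def roughness_and_radius(
    edge_points: np.ndarray, cells: list[Cell], spacing: float = DEFAULT_SPACING
) -> tuple[float, float]:
    """(roughness in lattice-cell units, radius in um) from edge distances."""
    if len(edge_points) < 2:
        raise ValueError("need at least two edge points")
    center = _area_weighted_center(cells)
    dists = np.hypot(*(np.asarray(edge_points) - center).T)
    return float(dists.std() / spacing), float(dists.mean())


def radius_from_inertia(cells: list[Cell]) -> float:
    """Disc-equivalent radius sqrt(2 I / A) from the colony moment of inertia."""
    if not cells:
        raise ValueError("radius needs at least one cell")
    center = _area_weighted_center(cells)
    areas = np.array([c.area for c in cells])
    centers = np.array([c.center for c in cells])
    r2 = ((centers - center) ** 2).sum(axis=1)
    inertia = float((areas * r2).sum())
    return math.sqrt(2.0 * inertia / areas.sum())


def active_cells(
    cells: list[Cell],
    nutrient: ChemicalField | None = None,
    params: GrowthParams | None = None,
    decay_factor: float = 2.0,
    criterion: str = "growth_rate",
) -> list[Cell]:
    """Cells growing within e^-decay_factor of the current maximum rate.

    Two readings of "within two exponential decays of the maximum" are
    supported.  The default, ``criterion='growth_rate'``, thresholds each
    cell's realized per-area elongation rate (``growth_rate_last / area``,
    which includes toxin/public-good modulation): a cell stalled by a toxin
    is not part of the actively expanding front even if nutrient would allow
    growth.  ``criterion='nutrient'`` thresholds the chemical-free Monod
    factor n/(kappa+n) sampled from the nutrient field instead.  Both are
    per-area quantities, so cell size does not enter; the threshold boundary
    is closed (>=).  A quiescent population (all rates zero) or a missing
    nutrient field yields every cell active.
    """
    if not cells:
        return []
    if criterion == "growth_rate":
        rates = np.array([c.growth_rate_last / c.area for c in cells])
        peak = rates.max()
        if peak <= 0.0:
            return list(cells)
        cutoff = peak * math.exp(-decay_factor)
        return [c for c, r in zip(cells, rates) if r >= cutoff]
    if criterion != "nutrient":
        raise ValueError("criterion must be 'growth_rate' or 'nutrient'")
    if nutrient is None:
        return list(cells)
    kappa = (params or GrowthParams()).kappa
    monod = np.array([sample_at(nutrient, c.center) for c in cells])
    monod = monod / (kappa + monod)
    cutoff = monod.max() * math.exp(-decay_factor)
    return [c for c, m in zip(cells, monod) if m >= cutoff]


def surviving_lineages(active: list[Cell]) -> tuple[int, int, int]:
    """(total, green, red) distinct lineage labels among the active cells."""
    green = {c.lineage for c in active if c.species == Species.GREEN}
    red = {c.lineage for c in active if c.species == Species.RED}
    return len(green | red), len(green), len(red)


def _render_species(
    cells: list[Cell], pixel: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-cell species raster: 0 background, 1 green, 2 red."""
    ends = np.array([c.endpoints for c in cells])  # (n, 2, 2)
    lo = ends.reshape(-1, 2).min(axis=0) - 1.0
    hi = ends.reshape(-1, 2).max(axis=0) + 1.0
    nx = int(math.ceil((hi[0] - lo[0]) / pixel))
    ny = int(math.ceil((hi[1] - lo[1]) / pixel))
    labels = np.zeros((nx, ny), dtype=np.uint8)
    best = np.full((nx, ny), np.inf)
    for c in cells:
        p0, p1 = c.endpoints
        r = c.diameter / 2.0
        i0 = max(0, int((min(p0[0], p1[0]) - r - lo[0]) / pixel))
        i1 = min(nx, int((max(p0[0], p1[0]) + r - lo[0]) / pixel) + 2)
        j0 = max(0, int((min(p0[1], p1[1]) - r - lo[1]) / pixel))
        j1 = min(ny, int((max(p0[1], p1[1]) + r - lo[1]) / pixel) + 2)
        xs = lo[0] + (np.arange(i0, i1) + 0.5) * pixel
        ys = lo[1] + (np.arange(j0, j1) + 0.5) * pixel
        px, py = np.meshgrid(xs, ys, indexing="ij")
        seg = p1 - p0
        seg2 = float(seg @ seg)
        if seg2 > 0:
            t = np.clip(((px - p0[0]) * seg[0] + (py - p0[1]) * seg[1]) / seg2, 0.0, 1.0)
        else:
            t = 0.0
        dx = px - (p0[0] + t * seg[0])
        dy = py - (p0[1] + t * seg[1])
        dist = np.hypot(dx, dy)
        window_best = best[i0:i1, j0:j1]
        hit = (dist <= r) & (dist < window_best)
        window_best[hit] = dist[hit]
        labels[i0:i1, j0:j1][hit] = 1 if c.species == Species.GREEN else 2
    return labels, best


def count_sectors(
    active: list[Cell],
    pixel: float = 0.5,
    min_cells: int = 100,
    return_labels: bool = False,
):
    """Number of connected same-species clusters of more than ``min_cells``.

    Active cells are rendered at ``pixel`` um/px with nearest-cell species
    ownership, smoothed by one pass of a 3x3 majority filter (background
    competes and wins ties), and labeled with 8-connectivity per species.
    Component pixel masses convert to cell counts through the snapshot's
    mean pixels-per-cell, making the threshold resolution-independent.
    """
    if not active:
        return (0, None) if return_labels else 0
    raster, _ = _render_species(active, pixel)
    kernel = np.ones((3, 3))
    counts = np.stack(
        [ndimage.convolve((raster == v).astype(float), kernel, mode="constant") for v in (0, 1, 2)]
    )
    smooth = np.argmax(counts, axis=0).astype(np.uint8)  # ties favor background
    occupied = int((smooth > 0).sum())
    if occupied == 0:
        return (0, None) if return_labels else 0
    pixels_per_cell = occupied / len(active)
    total = 0
    labeled_all = np.zeros_like(smooth, dtype=np.int32)
    next_label = 0
    for v in (1, 2):
        lab = cc_label(smooth == v, connectivity=2)
        sizes = np.bincount(lab.ravel())
        for comp in range(1, lab.max() + 1):
            if sizes[comp] > min_cells * pixels_per_cell * (1.0 + 1e-9):
                total += 1
                next_label += 1
                labeled_all[lab == comp] = next_label
    if return_labels:
        return total, labeled_all
    return total


def density_profile(
    cells: list[Cell],
    spacing: float = DEFAULT_SPACING,
    origin=None,
    shape: tuple[int, int] | None = None,
    species_filter=None,
) -> DensityField:
    """Cell-count density (cells per um^2) per lattice cell, by center."""
    sel = [c for c in cells if species_filter is None or c.species == species_filter]
    if origin is None or shape is None:
        if not sel:
            raise ValueError("empty selection needs explicit origin and shape")
        centers = np.array([c.center for c in sel])
        lo = np.floor((centers.min(axis=0) - spacing) / spacing) * spacing
        hi = centers.max(axis=0) + spacing
        shape = tuple((np.ceil((hi - lo) / spacing)).astype(int) + 1)
        origin = lo
    origin = np.asarray(origin, dtype=float)
    grid = np.zeros(shape)
    for c in sel:
        ix = int((c.center[0] - origin[0]) / spacing)
        iy = int((c.center[1] - origin[1]) / spacing)
        if not (0 <= ix < shape[0] and 0 <= iy < shape[1]):
            raise ValueError(f"cell {c.id} outside the density-profile grid")
        grid[ix, iy] += 1.0
    return DensityField(grid / spacing**2, spacing, origin)


def compute_metrics(
    cells: list[Cell],
    nutrient: ChemicalField | None = None,
    params: GrowthParams | None = None,
    time: float = 0.0,
    spacing: float = DEFAULT_SPACING,
    with_sectors: bool = False,
) -> MetricsRecord:
    """All scalar structure metrics for one snapshot."""
    lattice = occupancy_lattice(cells, spacing)
    edge = colony_edge(lattice)
    if len(edge) >= 2:
        rough, radius = roughness_and_radius(edge, cells, spacing)
    else:
        rough, radius = 0.0, 0.0
    active = active_cells(cells, nutrient, params)
    total_lin, green_lin, red_lin = surviving_lineages(active)
    return MetricsRecord(
        time=time,
        total_cells=len(cells),
        green_fraction=green_fraction(cells),
        roughness=rough,
        radius_edge=radius,
        radius_inertia=radius_from_inertia(cells),
        lineages=total_lin,
        green_lineages=green_lin,
        red_lineages=red_lin,
        sectors=count_sectors(active) if with_sectors else None,
    )
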