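"""Spherocylinder cell geometry, Hertzian contact forces, and overdamped motion.

Cells are rigid rods of length ``rod_length`` (distance between the two
hemispherical cap centers) with width ``diameter``, moving in a 2-D plane.
Mechanical interaction between two cells is evaluated by finding the closest
points between their axis segments, placing spheres of the cell diameter at
those points, and applying a Hertzian repulsion ``E d^(1/2) h^(3/2)`` when the
spheres overlap by ``h > 0``.  Motion is overdamped: velocity and angular
velocity are proportional to the summed contact forces and torques, with a
single lumped mobility prefactor (elasticity x timescale / drag x line
density) because inertia is negligible for micron-sized cells on a substrate.

Lengths are micrometers; the natural time unit tau is 30 minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from ._kernels import segment_closest_params

__all__ = [
    "Species",
    "Cell",
    "Contact",
    "MechParams",
    "closest_points",
    "hertzian_force",
    "step_motion",
    "neighbor_candidates",
    "ROD_LENGTH_FLOOR",
]

#: Rod length floor (um) used in the mobility denominators so that newborn,
#: nearly spherical cells do not acquire divergent velocities.
ROD_LENGTH_FLOOR = 0.5


class Species(IntEnum):
    GREEN = 0
    RED = 1


@dataclass
class Cell:
    """A single spherocylindrical cell.

    ``angle`` lies in [0, 2*pi); rods are unoriented, so ``angle`` and
    ``angle + pi`` describe the same physical axis.
    """

    id: int
    species: Species
    lineage: int
    center: np.ndarray
    angle: float
    rod_length: float
    diameter: float = 1.0
    division_length: float = 4.0
    growth_rate_last: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.rod_length < 0:
            raise ValueError("rod_length must be >= 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        self.angle = float(self.angle) % (2.0 * math.pi)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the rod axis."""
        return np.array([math.cos(self.angle), math.sin(self.angle)])

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Centers of the two hemispherical caps."""
        half = 0.5 * self.rod_length * self.axis
        return self.center - half, self.center + half

    @property
    def total_length(self) -> float:
        """Cap-to-cap outer length: rod plus one diameter."""
        return self.rod_length + self.diameter

    @property
    def area(self) -> float:
        """2-D footprint area of the spherocylinder."""
        return self.rod_length * self.diameter + math.pi * (self.diameter / 2.0) ** 2

    def copy(self) -> "Cell":
        return replace(self, center=self.center.copy())


@dataclass
class Contact:
    """A contact between two overlapping cells.

    ``normal`` is the unit vector from the closest point on ``cell_b`` toward
    the closest point on ``cell_a``; ``overlap`` is the sphere overlap
    ``diameter - |point_a - point_b|``.
    """

    cell_a: int
    cell_b: int
    point_a: np.ndarray
    point_b: np.ndarray
    overlap: float
    normal: np.ndarray


@dataclass
class MechParams:
    """Mechanical parameters.

    mobility is the lumped dimensionless prefactor (elasticity x time scale /
    drag x mass line density) of the overdamped equations of motion; its
    default makes an overlapping pair relax in a small fraction of a division
    time.  ``timestep`` is in tau units (tau = 30 min).
    """

    elasticity_E: float = 1.0
    sphere_diameter_d: float = 1.0
    mobility: float = 2.0e5
    timestep: float = 1.0e-4
    cap_mode: str = "per_cell"  # displacement-cap enforcement: "per_cell" | "substep"

    def __post_init__(self) -> None:
        for name in ("elasticity_E", "sphere_diameter_d", "mobility", "timestep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cap_mode not in ("per_cell", "substep"):
            raise ValueError("cap_mode must be 'per_cell' or 'substep'")


def closest_points(cell_a: Cell, cell_b: Cell) -> Contact | None:
    """Closest points between the axis segments of two cells.

    Returns a :class:`Contact` iff the cap spheres placed at the closest
    points overlap (``overlap > 0``); otherwise ``None``.  Zero-length rods
    degenerate to points; exactly parallel overlapping axes use the midpoint
    of the overlapping parameter interval as a deterministic tie-break.
    """
    ax, ay = cell_a.center
    bx, by = cell_b.center
    ua, va = math.cos(cell_a.angle), math.sin(cell_a.angle)
    ub, vb = math.cos(cell_b.angle), math.sin(cell_b.angle)
    s, t = segment_closest_params(
        ax, ay, ua, va, cell_a.rod_length, bx, by, ub, vb, cell_b.rod_length
    )
    pa = np.array([ax + s * ua, ay + s * va])
    pb = np.array([bx + t * ub, by + t * vb])
    diff = pa - pb
    dist = float(np.hypot(diff[0], diff[1]))
    d = 0.5 * (cell_a.diameter + cell_b.diameter)
    overlap = d - dist
    if overlap <= 0.0:
        return None
    if dist > 1e-12:
        normal = diff / dist
    else:
        # Exact axis crossing: push cell_a perpendicular to its own axis.
        normal = np.array([-va, ua])
    return Contact(cell_a.id, cell_b.id, pa, pb, overlap, normal)


def hertzian_force(overlap: float, params: MechParams) -> float:
    """Hertzian repulsion magnitude ``E d^(1/2) h^(3/2)`` (0 for ``h <= 0``)."""
    if overlap <= 0.0:
        return 0.0
    return params.elasticity_E * math.sqrt(params.sphere_diameter_d) * overlap**1.5


def step_motion(
    cells: list[Cell], contacts: list[Contact], params: MechParams
) -> list[Cell]:
    """One forward-Euler step of the overdamped equations of motion.

    Each contact contributes mobility * h^(3/2) / L to the center velocity of
    each partner (along +/- the contact normal) and
    mobility * 12 h^(3/2) / L^3 times the lever-arm torque to its angular
    velocity, with L the rod length floored at :data:`ROD_LENGTH_FLOOR`.
    Contact-free cells are returned unchanged (same objects).
    """
    index = {c.id: i for i, c in enumerate(cells)}
    vel = np.zeros((len(cells), 2))
    omega = np.zeros(len(cells))
    touched = np.zeros(len(cells), dtype=bool)
    for ct in contacts:
        h15 = max(ct.overlap, 0.0) ** 1.5
        if h15 == 0.0:
            continue
        for cid, point, sign in ((ct.cell_a, ct.point_a, 1.0), (ct.cell_b, ct.point_b, -1.0)):
            i = index[cid]
            cell = cells[i]
            L = max(cell.rod_length, ROD_LENGTH_FLOOR)
            normal = sign * ct.normal
            vel[i] += params.mobility * h15 / L * normal
            lever = point - cell.center
            torque = lever[0] * normal[1] - lever[1] * normal[0]
            omega[i] += params.mobility * 12.0 * h15 / L**3 * torque
            touched[i] = True
    out: list[Cell] = []
    dt = params.timestep
    for i, cell in enumerate(cells):
        if not touched[i]:
            out.append(cell)
            continue
        moved = cell.copy()
        moved.center = cell.center + vel[i] * dt
        moved.angle = (cell.angle + omega[i] * dt) % (2.0 * math.pi)
        out.append(moved)
    return out


def neighbor_candidates(cells: list[Cell], cutoff: float) -> list[tuple[int, int]]:
    """Candidate contact pairs via uniform spatial binning.

    Returns a duplicate-free superset of all pairs whose axis segments can be
    closer than one diameter, provided ``cutoff`` is at least the maximum
    cell extent (rod length) plus one diameter.  Pairs are (id_a, id_b) with
    id_a < id_b in list order.
    """
    n = len(cells)
    if n < 2:
        return []
    centers = np.array([c.center for c in cells])
    mins = centers.min(axis=0)
    ix = np.floor((centers[:, 0] - mins[0]) / cutoff).astype(np.int64)
    iy = np.floor((centers[:, 1] - mins[1]) / cutoff).astype(np.int64)
    bins: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        bins.setdefault((int(ix[i]), int(iy[i])), []).append(i)
    cutoff2 = cutoff * cutoff
    pairs: list[tuple[int, int]] = []
    for (bx, by), members in bins.items():
        for dx in (0, 1):
            for dy in ((0, 1) if dx == 0 else (-1, 0, 1)):
                other = bins.get((bx + dx, by + dy))
                if other is None:
                    continue
                if dx == 0 and dy == 0:
                    for a in range(len(members)):
                        for b in range(a + 1, len(members)):
                            i, j = members[a], members[b]
                            d = centers[i] - centers[j]
                            if d[0] * d[0] + d[1] * d[1] <= cutoff2:
                                pairs.append((cells[i].id, cells[j].id))
                else:
                    for i in members:
                        for j in other:
                            d = centers[i] - centers[j]
                            if d[0] * d[0] + d[1] * d[1] <= cutoff2:
                                pairs.append((cells[i].id, cells[j].id))
    return pairs
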