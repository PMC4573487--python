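"""Initial-condition generators and deterministic fixture colonies.

Seed cells are placed on a regular sub-grid of a 60x60 um^2 square (16x16,
8x8 or 4x4 for the high/medium/low densities of 256/64/16 cells).  The
well-mixed mode lays species out in an alternating pattern that hits the
requested abundance exactly; the random mode keeps the grid positions (with
jitter) but permutes the species labels randomly under the same exact
counts.  Orientations and initial lengths are random in both modes.
"""

from __future__ import annotations

import math

import numpy as np

from .config import DENSITY_COUNTS, SEED_BOX_SIZE
from .growth import DivisionRule, sample_division_length
from .mechanics import Cell, Species

__all__ = ["seed_wellmixed", "seed_random", "species_counts", "make_fixture_colony"]

_INITIAL_ROD_RANGE = (1.0, 2.0)  # um; total length 2-3 um at diameter 1


def species_counts(density: str, ratio: tuple[int, int]) -> tuple[int, int]:
    """Exact (green, red) counts for a density and abundance ratio.

    Non-integral splits are rounded deterministically in green's favor.
    """
    n = DENSITY_COUNTS[density]
    a, b = int(ratio[0]), int(ratio[1])
    if a <= 0 or b <= 0:
        raise ValueError("ratio entries must be positive")
    n_green = -((-n * a) // (a + b))  # ceil toward green
    return n_green, n - n_green


def _grid_positions(n: int) -> tuple[np.ndarray, float, int]:
    m = int(round(math.sqrt(n)))
    if m * m != n:
        raise ValueError(f"seed count {n} is not a perfect square")
    pitch = SEED_BOX_SIZE / m
    coords = -SEED_BOX_SIZE / 2.0 + (np.arange(m) + 0.5) * pitch
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()]), pitch, m

def _alternating_labels(n: int, m: int, n_green: int) -> np.ndarray:
    """Species labels alternating with period (a+b) scaled to exact counts.

    The repeating green/red pattern is laid out row-major and each row's
    segment is rotated by its row index, which turns the 1:1 case into a
    checkerboard and keeps the per-row multisets (hence the exact counts)
    unchanged for every ratio.
    """
    n_red = n - n_green
    g = math.gcd(n_green, n_red) if n_red else n_green
    period_green = n_green // g if g else 0
    period = n // g if g else n
    base = np.array(
        [Species.GREEN if k % period < period_green else Species.RED for k in range(n)],
        dtype=np.int8,
    )
    out = np.empty(n, dtype=np.int8)
    for i in range(m):
        row = base[i * m : (i + 1) * m]
        out[i * m : (i + 1) * m] = np.roll(row, -i)
    return out


def _build_cells(
    positions: np.ndarray,
    labels: np.ndarray,
    rule: DivisionRule,
    rng: np.random.Generator,
) -> list[Cell]:
    cells = []
    for i, (pos, lab) in enumerate(zip(positions, labels)):
        angle = rng.uniform(0.0, 2.0 * math.pi)
        rod = rng.uniform(*_INITIAL_ROD_RANGE)
        div = sample_division_length(rule, rng)
        cells.append(
            Cell(
                id=i,
                species=Species(int(lab)),
                lineage=i,
                center=np.asarray(pos, dtype=float),
                angle=angle,
                rod_length=rod,
                division_length=div,
            )
        )
    return cells


def seed_wellmixed(
    density: str,
    ratio: tuple[int, int],
    rng: np.random.Generator,
    rule: DivisionRule | None = None,
) -> list[Cell]:
    """Alternating-pattern seeding with exact species counts."""
    rule = rule or DivisionRule()
    n = DENSITY_COUNTS[density]
    n_green, _ = species_counts(density, ratio)
    positions, _, m = _grid_positions(n)
    labels = _alternating_labels(n, m, n_green)
    return _build_cells(positions, labels, rule, rng)


def seed_random(
    density: str,
    ratio: tuple[int, int],
    rng: np.random.Generator,
    rule: DivisionRule | None = None,
    jitter: float = 0.25,
) -> list[Cell]:
    """Random-permutation seeding: grid positions with jitter, shuffled labels."""
    rule = rule or DivisionRule()
    n = DENSITY_COUNTS[density]
    n_green, n_red = species_counts(density, ratio)
    positions, pitch, _ = _grid_positions(n)
    positions = positions + rng.uniform(-jitter * pitch, jitter * pitch, size=positions.shape)
    labels = np.array([Species.GREEN] * n_green + [Species.RED] * n_red, dtype=np.int8)
    rng.shuffle(labels)
    return _build_cells(positions, labels, rule, rng)


# ---------------------------------------------------------------------------
# Deterministic fixture colonies for metric tests
# ---------------------------------------------------------------------------

def _disc_centers(n_cells: int, pitch: float) -> np.ndarray:
    """First n_cells square-grid points ordered by distance from the origin."""
    m = int(math.ceil(math.sqrt(n_cells / math.pi) * 2.0)) + 2
    coords = (np.arange(-m, m + 1)) * pitch
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    r2 = (pts**2).sum(axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], r2))
    return pts[order[:n_cells]]


def make_fixture_colony(
    shape: str,
    n_cells: int,
    pitch: float = 1.5,
    rod_length: float = 1.0,
    radius: float | None = None,
    n_stripes: int = 12,
    stripe_rows: int = 20,
    inner_radius: float | None = None,
    species: str = "green",
):
    """Deterministic colony layouts for exercising the structure metrics.

    shape 'disc': cells on a square grid filling a disc (``radius`` wins over
    ``n_cells`` when given).  'half_discs': a disc with the left half green
    and the right half red.  'stripes': ``n_stripes`` vertical single-species
    bands of ``n_cells // n_stripes`` cells each, alternating species.
    'annulus': a ring between ``inner_radius`` and the implied outer radius.
    All cells are axis-aligned rods of identical size on a ``pitch`` grid and
    are marked actively growing.  Returns a :class:`~socolony.io.Snapshot`.
    """
    from .io import Snapshot, cells_to_frame

    base_species = Species.GREEN if species == "green" else Species.RED
    if shape in ("disc", "half_discs"):
        if radius is not None:
            n_cells = max(1, int(round(math.pi * radius**2 / pitch**2)))
        centers = _disc_centers(n_cells, pitch)
        if shape == "half_discs":
            labels = np.where(centers[:, 0] < 0, Species.GREEN, Species.RED)
        else:
            labels = np.full(len(centers), base_species)
    elif shape == "annulus":
        if radius is None or inner_radius is None:
            raise ValueError("annulus needs radius and inner_radius")
        n_outer = int(round(math.pi * radius**2 / pitch**2))
        centers = _disc_centers(n_outer, pitch)
        keep = (centers**2).sum(axis=1) >= inner_radius**2
        centers = centers[keep]
        labels = np.full(len(centers), base_species)
    elif shape == "stripes":
        per = n_cells // n_stripes
        cols = max(1, per // stripe_rows)
        centers_list = []
        labels_list = []
        x0 = 0.0
        for s in range(n_stripes):
            k = 0
            for cc in range(cols + 1):
                for r in range(stripe_rows):
                    if k >= per:
                        break
                    centers_list.append([x0 + cc * pitch, r * pitch])
                    labels_list.append(Species.GREEN if s % 2 == 0 else Species.RED)
                    k += 1
            x0 += (cols + 1) * pitch
        centers = np.array(centers_list)
        labels = np.array(labels_list)
    else:
        raise ValueError(f"unknown fixture shape {shape!r}")

    cells = [
        Cell(
            id=i,
            species=Species(int(lab)),
            lineage=i,
            center=np.asarray(pos, dtype=float),
            angle=0.0,
            rod_length=rod_length,
            growth_rate_last=1.0,
        )
        for i, (pos, lab) in enumerate(zip(centers, labels))
    ]
    return Snapshot(time=0.0, cells=cells_to_frame(cells))
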