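import math

import numpy as np
import pytest

from socolony.mechanics import Cell, Species


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_cell(
    cid=0,
    x=0.0,
    y=0.0,
    angle=0.0,
    rod=2.0,
    species=Species.GREEN,
    lineage=None,
    diameter=1.0,
    division_length=4.0,
):
    return Cell(
        id=cid,
        species=species,
        lineage=cid if lineage is None else lineage,
        center=np.array([x, y], dtype=float),
        angle=angle,
        rod_length=rod,
        diameter=diameter,
        division_length=division_length,
    )


def random_cell(rng, cid=0, box=6.0, max_rod=4.0):
    return make_cell(
        cid=cid,
        x=rng.uniform(-box, box),
        y=rng.uniform(-box, box),
        angle=rng.uniform(0, 2 * math.pi),
        rod=rng.uniform(0.0, max_rod),
    )


def brute_force_min_distance(cell_a, cell_b, n=100):
    """Dense-sampling oracle for the segment-segment minimum distance.

    Samples an n x n grid of parameter pairs, then refines the same grid
    inside the winning cell's neighborhood so the sampling error is far
    below the comparison tolerance.  Independent of the clamped-quadratic
    closest-point routine under test.
    """

    def scan(lo_a, hi_a, lo_b, hi_b):
        sa = np.linspace(lo_a, hi_a, n)
        sb = np.linspace(lo_b, hi_b, n)
        pa = cell_a.center[None, :] + sa[:, None] * cell_a.axis[None, :]
        pb = cell_b.center[None, :] + sb[:, None] * cell_b.axis[None, :]
        diff = pa[:, None, :] - pb[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        k = np.unravel_index(np.argmin(d), d.shape)
        return float(d[k]), sa[k[0]], sb[k[1]], (sa[1] - sa[0] if n > 1 else 0), (
            sb[1] - sb[0] if n > 1 else 0
        )

    half_a, half_b = cell_a.rod_length / 2, cell_b.rod_length / 2
    best, sa0, sb0, da, db = scan(-half_a, half_a, -half_b, half_b)
    for _ in range(2):  # two refinement passes around the current minimizer
        best, sa0, sb0, da, db = scan(
            max(-half_a, sa0 - da), min(half_a, sa0 + da),
            max(-half_b, sb0 - db), min(half_b, sb0 + db),
        )
    return best
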