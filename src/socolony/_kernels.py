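"""Numba-compiled inner loops shared by the scalar API and the engine.

The segment-segment closest-point routine follows the standard clamped
quadratic minimization for capsule collision tests, with one addition: for
exactly parallel segments whose projections overlap, the minimizer is
non-unique and the midpoint of the overlapping parameter interval is used as
a deterministic tie-break.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _seg_params01(p1x, p1y, d1x, d1y, p2x, p2y, d2x, d2y):
    """Closest-point parameters (s, t) in [0, 1] for two segments P1+s*d1, P2+t*d2."""
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    rx = p1x - p2x
    ry = p1y - p2y
    f = d2x * rx + d2y * ry
    if a <= _EPS and e <= _EPS:
        return 0.0, 0.0
    if a <= _EPS:
        t = f / e
        t = min(max(t, 0.0), 1.0)
        return 0.0, t
    c = d1x * rx + d1y * ry
    if e <= _EPS:
        s = -c / a
        s = min(max(s, 0.0), 1.0)
        return s, 0.0
    b = d1x * d2x + d1y * d2y
    denom = a * e - b * b
    if denom > 1e-10 * a * e:
        s = (b * f - c * e) / denom
        s = min(max(s, 0.0), 1.0)
    else:
        # Parallel axes: midpoint of the overlapping projection interval.
        s0 = -c / a
        s1 = (b - c) / a
        lo = min(s0, s1)
        hi = max(s0, s1)
        if hi < 0.0:
            s = 0.0
        elif lo > 1.0:
            s = 1.0
        else:
            s = 0.5 * (max(lo, 0.0) + min(hi, 1.0))
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = min(max(-c / a, 0.0), 1.0)
    elif t > 1.0:
        t = 1.0
        s = min(max((b - c) / a, 0.0), 1.0)
    return s, t


@njit(cache=True)
def segment_closest_params(ax, ay, ux, uy, la, bx, by, vx, vy, lb):
    """Closest-point offsets (s, t) from the segment centers.

    Segment a is {(ax, ay) + s*(ux, uy) : s in [-la/2, la/2]} and likewise
    for b; (ux, uy), (vx, vy) are unit axis vectors.
    """
    p1x = ax - 0.5 * la * ux
    p1y = ay - 0.5 * la * uy
    p2x = bx - 0.5 * lb * vx
    p2y = by - 0.5 * lb * vy
    s01, t01 = _seg_params01(p1x, p1y, la * ux, la * uy, p2x, p2y, lb * vx, lb * vy)
    return (s01 - 0.5) * la, (t01 - 0.5) * lb


@njit(cache=True)
def collect_pairs(order, starts, nbx, nby, x, y, reach, out_i, out_j):
    """Half-neighborhood sweep over a cell-linked grid.

    ``order`` holds cell indices sorted by bin id (binx*nby + biny);
    ``starts`` gives the slice of ``order`` per bin id.  ``reach[i]`` is the
    contact reach of cell i (half its axis length plus half a diameter, plus
    any safety margin); a pair is emitted when the center distance is at
    most reach[i] + reach[j].  The bin size must be at least the maximum
    pair reach so a 3x3 neighborhood suffices.  Returns the pair count, or
    -1 if the output arrays are too small.
    """
    cap = out_i.shape[0]
    count = 0
    for bx in range(nbx):
        for by in range(nby):
            b0 = bx * nby + by
            lo = starts[b0]
            hi = starts[b0 + 1]
            if lo == hi:
                continue
            # same bin
            for p in range(lo, hi):
                i = order[p]
                for q in range(p + 1, hi):
                    j = order[q]
                    dx = x[i] - x[j]
                    dy = y[i] - y[j]
                    rr = reach[i] + reach[j]
                    if dx * dx + dy * dy <= rr * rr:
                        if count >= cap:
                            return -1
                        out_i[count] = i
                        out_j[count] = j
                        count += 1
            # forward neighbor bins: (0,1), (1,-1), (1,0), (1,1)
            for k in range(4):
                if k == 0:
                    obx, oby = bx, by + 1
                elif k == 1:
                    obx, oby = bx + 1, by - 1
                elif k == 2:
                    obx, oby = bx + 1, by
                else:
                    obx, oby = bx + 1, by + 1
                if obx < 0 or obx >= nbx or oby < 0 or oby >= nby:
                    continue
                b1 = obx * nby + oby
                lo1 = starts[b1]
                hi1 = starts[b1 + 1]
                for p in range(lo, hi):
                    i = order[p]
                    for q in range(lo1, hi1):
                        j = order[q]
                        dx = x[i] - x[j]
                        dy = y[i] - y[j]
                        rr = reach[i] + reach[j]
                        if dx * dx + dy * dy <= rr * rr:
                            if count >= cap:
                                return -1
                            out_i[count] = i
                            out_j[count] = j
                            count += 1
    return count


@njit(cache=True)
def accumulate_contact_velocities(
    x, y, ca, sa, rod, pair_i, pair_j, npairs, d, mobility, lfloor, vx, vy, om
):
    """Sum overdamped contact velocities and angular velocities in place.

    For each candidate pair, finds the closest axis points; when the cap
    spheres overlap (h > 0) adds mobility*h^(3/2)/L to each partner's center
    velocity along the contact normal and mobility*12*h^(3/2)/L^3 times the
    lever-arm torque to its angular velocity.  Returns the number of actual
    contacts.
    """
    ncontacts = 0
    for k in range(npairs):
        i = pair_i[k]
        j = pair_j[k]
        s, t = segment_closest_params(
            x[i], y[i], ca[i], sa[i], rod[i], x[j], y[j], ca[j], sa[j], rod[j]
        )
        pax = x[i] + s * ca[i]
        pay = y[i] + s * sa[i]
        pbx = x[j] + t * ca[j]
        pby = y[j] + t * sa[j]
        dx = pax - pbx
        dy = pay - pby
        dist = math.sqrt(dx * dx + dy * dy)
        h = d - dist
        if h <= 0.0:
            continue
        ncontacts += 1
        h15 = h * math.sqrt(h)
        if dist > 1e-12:
            nx = dx / dist
            ny = dy / dist
        else:
            nx = -sa[i]
            ny = ca[i]
        li = rod[i] if rod[i] > lfloor else lfloor
        lj = rod[j] if rod[j] > lfloor else lfloor
        fi = mobility * h15 / li
        fj = mobility * h15 / lj
        vx[i] += fi * nx
        vy[i] += fi * ny
        vx[j] -= fj * nx
        vy[j] -= fj * ny
        # torque = lever x force direction (z component)
        ti = (pax - x[i]) * ny - (pay - y[i]) * nx
        tj = (pbx - x[j]) * (-ny) - (pby - y[j]) * (-nx)
        om[i] += mobility * 12.0 * h15 / (li * li * li) * ti
        om[j] += mobility * 12.0 * h15 / (lj * lj * lj) * tj
    return ncontacts


@njit(cache=True)
def ftcs_nutrient_substeps(grid, rho, D, alpha, kappa, dt, spacing, nsub):
    """nsub fused FTCS steps of dn/dt = D lap(n) - alpha*rho*n/(kappa+n).

    The boundary ring is held at the external-source value 1; values are
    clipped at 0 to absorb rounding.
    """
    nx, ny = grid.shape
    inv_h2 = 1.0 / (spacing * spacing)
    work = np.empty_like(grid)
    for _ in range(nsub):
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                g = grid[i, j]
                lap = (
                    grid[i + 1, j] + grid[i - 1, j] + grid[i, j + 1] + grid[i, j - 1]
                    - 4.0 * g
                ) * inv_h2
                val = g + dt * (D * lap - alpha * rho[i, j] * g / (kappa + g))
                work[i, j] = val if val > 0.0 else 0.0
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                grid[i, j] = work[i, j]
        for i in range(nx):
            grid[i, 0] = 1.0
            grid[i, ny - 1] = 1.0
        for j in range(ny):
            grid[0, j] = 1.0
            grid[nx - 1, j] = 1.0


@njit(cache=True)
def ftcs_chemical_substeps(grid, rho, D, beta, dt, spacing, nsub):
    """nsub fused FTCS steps of dc/dt = D lap(c) + rho - beta*c, absorbing ring."""
    nx, ny = grid.shape
    inv_h2 = 1.0 / (spacing * spacing)
    work = np.empty_like(grid)
    for _ in range(nsub):
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                g = grid[i, j]
                lap = (
                    grid[i + 1, j] + grid[i - 1, j] + grid[i, j + 1] + grid[i, j - 1]
                    - 4.0 * g
                ) * inv_h2
                val = g + dt * (D * lap + rho[i, j] - beta * g)
                work[i, j] = val if val > 0.0 else 0.0
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                grid[i, j] = work[i, j]
        for i in range(nx):
            grid[i, 0] = 0.0
            grid[i, ny - 1] = 0.0
        for j in range(ny):
            grid[0, j] = 0.0
            grid[nx - 1, j] = 0.0


@njit(cache=True)
def deposit_axis_samples(x, y, ca, sa, rod, weight, gx0, gy0, inv_spacing, nx, ny, nsamp, out):
    """Deposit per-cell weights onto a lattice via nsamp points along each axis.

    Each cell's ``weight`` is split evenly over ``nsamp`` sample points spread
    from cap center to cap center; each sample lands in the lattice cell that
    contains it.  Returns the number of out-of-grid samples (callers treat a
    nonzero value as an error).
    """
    n = x.shape[0]
    misses = 0
    for i in range(n):
        w = weight[i] / nsamp
        for m in range(nsamp):
            frac = (m + 0.5) / nsamp - 0.5
            px = x[i] + frac * rod[i] * ca[i]
            py = y[i] + frac * rod[i] * sa[i]
            ix = int((px - gx0) * inv_spacing)
            iy = int((py - gy0) * inv_spacing)
            if px < gx0 or py < gy0 or ix >= nx or iy >= ny:
                misses += 1
                continue
            out[ix, iy] += w
    return misses
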