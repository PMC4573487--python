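"""Array-based simulation engine.

Holds the colony as a structure of numpy arrays and advances the fixed
event order per mechanics step: rasterize cell densities -> sub-step the
chemical fields -> elongate -> divide -> resolve contacts and move.  The
per-pair contact work runs in numba kernels; everything else is vectorized.

The mechanics step honours a displacement cap of 0.1 cell diameters: when
the proposed overdamped displacement of any cell (including cap-end motion
from rotation) exceeds the cap, the step is subdivided with forces
recomputed in each sub-step, which is how the configured timestep is
"halved automatically" near hard overlaps (e.g. directly after seeding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import (
    accumulate_contact_velocities,
    collect_pairs,
    deposit_axis_samples,
    ftcs_chemical_substeps,
    ftcs_nutrient_substeps,
)
from .config import SimulationConfig
from .fields import (
    ChemicalField,
    DensityField,
    chemical_step_inplace,
    nutrient_step_inplace,
    stable_dt,
)
from .io import Snapshot, SNAPSHOT_COLUMNS
from .mechanics import ROD_LENGTH_FLOOR, Species
from .seeding import seed_random, seed_wellmixed

__all__ = ["Colony", "run_engine"]

_DISPLACEMENT_CAP_FRACTION = 0.1
_MAX_MECH_SUBSTEPS = 100_000
_SAFETY = 0.9  # fraction of the FTCS stability bound actually used


class Colony:
    """Structure-of-arrays colony state with amortized growth."""

    __slots__ = (
        "n", "x", "y", "angle", "rod", "divlen", "grl",
        "species", "lineage", "ids", "diameter", "next_id",
    )

    def __init__(self, cells, capacity: int | None = None):
        n = len(cells)
        cap = max(capacity or 0, 2 * n, 64)
        self.n = n
        self.x = np.zeros(cap)
        self.y = np.zeros(cap)
        self.angle = np.zeros(cap)
        self.rod = np.zeros(cap)
        self.divlen = np.zeros(cap)
        self.grl = np.zeros(cap)
        self.species = np.zeros(cap, dtype=np.int8)
        self.lineage = np.zeros(cap, dtype=np.int64)
        self.ids = np.zeros(cap, dtype=np.int64)
        for i, c in enumerate(cells):
            self.x[i], self.y[i] = c.center
            self.angle[i] = c.angle
            self.rod[i] = c.rod_length
            self.divlen[i] = c.division_length
            self.grl[i] = c.growth_rate_last
            self.species[i] = int(c.species)
            self.lineage[i] = c.lineage
            self.ids[i] = c.id
        self.diameter = cells[0].diameter if cells else 1.0
        self.next_id = int(self.ids[:n].max()) + 1 if n else 0

    def _ensure(self, extra: int) -> None:
        cap = self.x.shape[0]
        if self.n + extra <= cap:
            return
        new_cap = max(2 * cap, self.n + extra)
        for name in ("x", "y", "angle", "rod", "divlen", "grl", "species", "lineage", "ids"):
            old = getattr(self, name)
            grown = np.zeros(new_cap, dtype=old.dtype)
            grown[: self.n] = old[: self.n]
            setattr(self, name, grown)

    @property
    def area(self) -> np.ndarray:
        d = self.diameter
        return self.rod[: self.n] * d + math.pi * (d / 2.0) ** 2

    def to_frame(self) -> pd.DataFrame:
        n = self.n
        names = np.where(self.species[:n] == int(Species.GREEN), "green", "red")
        return pd.DataFrame(
            {
                "id": self.ids[:n].copy(),
                "species": names,
                "lineage": self.lineage[:n].copy(),
                "x": self.x[:n].copy(),
                "y": self.y[:n].copy(),
                "angle": self.angle[:n].copy(),
                "rod_length": self.rod[:n].copy(),
                "diameter": np.full(n, self.diameter),
                "division_length": self.divlen[:n].copy(),
                "growth_rate_last": self.grl[:n].copy(),
            },
            columns=SNAPSHOT_COLUMNS,
        )


@dataclass
class _RunState:
    time: float = 0.0
    step: int = 0
    snapshots: list = field(default_factory=list)
    metrics_rows: list = field(default_factory=list)


def _density(colony: Colony, mask, grid_shape, origin, spacing, samples=9) -> np.ndarray:
    n = colony.n
    out = np.zeros(grid_shape)
    if mask is None:
        idx = slice(0, n)
        weights = colony.area
    else:
        idx = np.nonzero(mask[:n])[0]
        if idx.size == 0:
            return out
        weights = colony.area[idx]
    ca = np.cos(colony.angle[idx])
    sa = np.sin(colony.angle[idx])
    misses = deposit_axis_samples(
        colony.x[idx], colony.y[idx], ca, sa, colony.rod[idx],
        np.ascontiguousarray(weights), float(origin[0]), float(origin[1]),
        1.0 / spacing, grid_shape[0], grid_shape[1], samples, out,
    )
    if misses:
        raise RuntimeError(
            "colony outgrew the chemical lattice; increase domain_size"
        )
    out /= spacing * spacing
    return out


def _divide_due(colony: Colony, rng_len, rng_ang, rule) -> int:
    """Split every cell at or beyond its division threshold; returns count."""
    n = colony.n
    d = colony.diameter
    if rule.threshold_on == "total":
        due = np.nonzero(colony.rod[:n] + d >= colony.divlen[:n])[0]
    else:
        due = np.nonzero(colony.rod[:n] >= colony.divlen[:n])[0]
    if due.size == 0:
        return 0
    colony._ensure(due.size)
    for i in due:
        rod_child = max(0.0, (colony.rod[i] - d) / 2.0)
        off = (rod_child + d) / 2.0
        ax, ay = math.cos(colony.angle[i]), math.sin(colony.angle[i])
        cx, cy = colony.x[i], colony.y[i]
        parent_angle = colony.angle[i]
        j = colony.n
        colony.n += 1
        # daughter occupying the -axis half keeps the parent's slot
        for slot, sign in ((i, -1.0), (j, +1.0)):
            noise = rng_ang.uniform(-rule.angle_noise, rule.angle_noise) if rule.angle_noise else 0.0
            colony.x[slot] = cx + sign * off * ax
            colony.y[slot] = cy + sign * off * ay
            colony.angle[slot] = (parent_angle + noise) % (2.0 * math.pi)
            colony.rod[slot] = rod_child
            colony.divlen[slot] = min(max(rng_len.normal(rule.mean, rule.sd), rule.lower), rule.upper)
            colony.grl[slot] = colony.grl[i]
            colony.species[slot] = colony.species[i]
            colony.lineage[slot] = colony.lineage[i]
            colony.ids[slot] = colony.next_id
            colony.next_id += 1
    return int(due.size)


class _PairBuffer:
    def __init__(self):
        self.i = np.zeros(1024, dtype=np.int64)
        self.j = np.zeros(1024, dtype=np.int64)

    def grow(self):
        cap = 2 * self.i.shape[0]
        self.i = np.zeros(cap, dtype=np.int64)
        self.j = np.zeros(cap, dtype=np.int64)


def _candidate_pairs(colony: Colony, buf: _PairBuffer) -> int:
    n = colony.n
    if n < 2:
        return 0
    x = colony.x[:n]
    y = colony.y[:n]
    reach = 0.5 * (colony.rod[:n] + colony.diameter) + 1e-9
    cutoff = 2.0 * float(reach.max())
    xmin, ymin = x.min(), y.min()
    nbx = int((x.max() - xmin) / cutoff) + 1
    nby = int((y.max() - ymin) / cutoff) + 1
    binx = ((x - xmin) / cutoff).astype(np.int64)
    biny = ((y - ymin) / cutoff).astype(np.int64)
    bin_id = binx * nby + biny
    order = np.argsort(bin_id, kind="stable")
    starts = np.searchsorted(bin_id[order], np.arange(nbx * nby + 1))
    while True:
        count = collect_pairs(order, starts, nbx, nby, x, y, reach, buf.i, buf.j)
        if count >= 0:
            return count
        buf.grow()


def _mechanics_step(
    colony: Colony, buf: _PairBuffer, mobility: float, dt: float,
    cap_mode: str = "per_cell",
) -> None:
    """Advance the overdamped contact dynamics by one timestep.

    The displacement cap (0.1 cell diameters per force evaluation,
    including cap-end motion from rotation) is enforced either per cell —
    an offending cell's translation and rotation are scaled down together,
    leaving the rest of the colony on the full step (default; in a growing
    colony only the extreme tail of the jostle distribution is touched) —
    or by global sub-stepping with forces recomputed each sub-step
    (``cap_mode='substep'``), which resolves the fastest cell exactly at a
    cost proportional to its speed.
    """
    n = colony.n
    d = colony.diameter
    cap = _DISPLACEMENT_CAP_FRACTION * d
    remaining = dt
    guard = 0
    while remaining > 0.0:
        guard += 1
        if guard > _MAX_MECH_SUBSTEPS:
            raise RuntimeError(
                "mechanics step failed to satisfy the displacement cap; "
                "the configuration is mechanically unstable"
            )
        npairs = _candidate_pairs(colony, buf)
        if npairs == 0:
            return
        vx = np.zeros(n)
        vy = np.zeros(n)
        om = np.zeros(n)
        ca = np.cos(colony.angle[:n])
        sa = np.sin(colony.angle[:n])
        ncontacts = accumulate_contact_velocities(
            colony.x[:n], colony.y[:n], ca, sa, colony.rod[:n],
            buf.i, buf.j, npairs, d, mobility, ROD_LENGTH_FLOOR, vx, vy, om,
        )
        if ncontacts == 0:
            return
        speed = np.sqrt(vx * vx + vy * vy) + np.abs(om) * (colony.rod[:n] / 2.0)
        if cap_mode == "per_cell":
            disp = speed * remaining
            over = disp > cap
            if np.any(over):
                scale = np.ones(n)
                scale[over] = cap / disp[over]
                vx *= scale
                vy *= scale
                om *= scale
            colony.x[:n] += vx * remaining
            colony.y[:n] += vy * remaining
            colony.angle[:n] = (colony.angle[:n] + om * remaining) % (2.0 * math.pi)
            return
        vmax = float(speed.max())
        sub = remaining
        if vmax * sub > cap:
            sub = cap / vmax
        colony.x[:n] += vx * sub
        colony.y[:n] += vy * sub
        colony.angle[:n] = (colony.angle[:n] + om * sub) % (2.0 * math.pi)
        remaining -= sub


def run_engine(config: SimulationConfig, collect_metrics_fn=None):
    """Run a full colony simulation; returns (snapshots, metrics DataFrame).

    ``collect_metrics_fn(snapshot) -> dict`` is called at every snapshot
    cadence (and at the final state) to build the metrics time series; the
    default records only time and cell counts, the public ``simulate.run``
    wires in the metrics module.
    """
    seq = np.random.SeedSequence(config.seed)
    seeds = seq.spawn(3)
    rng_seed = np.random.default_rng(seeds[0])
    rng_divlen = np.random.default_rng(seeds[1])
    rng_divang = np.random.default_rng(seeds[2])

    seeder = seed_wellmixed if config.seeding_mode == "wellmixed" else seed_random
    cells = seeder(config.density, config.ratio, rng_seed, config.division)
    if config.swap_species:
        for c in cells:
            c.species = Species(1 - int(c.species))
    colony = Colony(cells, capacity=config.max_cells + 256)

    L = config.domain_size
    spacing = config.grid_spacing
    ngrid = int(round(L / spacing))
    origin = np.array([-L / 2.0, -L / 2.0])
    shape = (ngrid, ngrid)
    nutrient = np.ones(shape)
    inter = config.interaction
    chem_by_green = np.zeros(shape) if inter.produces_green else None
    chem_by_red = np.zeros(shape) if inter.produces_red else None
    xi_by_species = np.array([inter.xi_green, inter.xi_red])

    dt = config.mech.timestep
    mobility = config.mech.mobility
    g = config.growth.g
    kappa = config.growth.kappa
    buf = _PairBuffer()
    state = _RunState()
    next_snapshot = 0.0

    def fields_dict():
        out = {
            "nutrient": ChemicalField(nutrient.copy(), spacing, origin.copy(), "dirichlet_one")
        }
        if chem_by_green is not None:
            out["chem_by_green"] = ChemicalField(
                chem_by_green.copy(), spacing, origin.copy(), "reactive"
            )
        if chem_by_red is not None:
            out["chem_by_red"] = ChemicalField(
                chem_by_red.copy(), spacing, origin.copy(), "reactive"
            )
        out["density"] = DensityField(rho_all.copy(), spacing, origin.copy())
        return out

    def record():
        snap = Snapshot(
            time=state.time,
            cells=colony.to_frame(),
            fields=fields_dict() if config.record_fields else {},
        )
        state.snapshots.append(snap)
        if collect_metrics_fn is not None:
            state.metrics_rows.append(collect_metrics_fn(snap))
        else:
            green = int((colony.species[: colony.n] == int(Species.GREEN)).sum())
            state.metrics_rows.append(
                {"time": state.time, "total_cells": colony.n,
                 "green_fraction": green / colony.n}
            )

    rho_all = _density(colony, None, shape, origin, spacing)
    record()
    next_snapshot = config.snapshot_every

    green_mask = None
    red_mask = None
    while colony.n < config.max_cells and state.step < config.max_steps:
        state.step += 1
        n = colony.n
        # 1. densities
        if (state.step - 1) % config.density_every == 0:
            rho_all = _density(colony, None, shape, origin, spacing)
            if chem_by_green is not None:
                green_mask = colony.species == int(Species.GREEN)
                rho_green = _density(colony, green_mask, shape, origin, spacing)
            if chem_by_red is not None:
                red_mask = colony.species == int(Species.RED)
                rho_red = _density(colony, red_mask, shape, origin, spacing)
        # 2. chemistry sub-steps
        rate_n = config.nutrient.alpha_n * float(rho_all.max()) / kappa
        dt_lim = _SAFETY * stable_dt(config.nutrient.D, spacing, rate_n)
        if chem_by_green is not None or chem_by_red is not None:
            dt_lim = min(
                dt_lim, _SAFETY * stable_dt(config.chemical.D, spacing, config.chemical.beta)
            )
        if config.quasi_steady_chem:
            _relax_fields(
                nutrient, chem_by_green, chem_by_red, rho_all,
                rho_green if chem_by_green is not None else None,
                rho_red if chem_by_red is not None else None,
                config, dt_lim, spacing,
            )
        else:
            nsub = max(1, int(math.ceil(dt / dt_lim)))
            sub = dt / nsub
            ftcs_nutrient_substeps(
                nutrient, rho_all, config.nutrient.D, config.nutrient.alpha_n,
                kappa, sub, spacing, nsub,
            )
            if chem_by_green is not None:
                ftcs_chemical_substeps(
                    chem_by_green, rho_green, config.chemical.D, config.chemical.beta,
                    sub, spacing, nsub,
                )
            if chem_by_red is not None:
                ftcs_chemical_substeps(
                    chem_by_red, rho_red, config.chemical.D, config.chemical.beta,
                    sub, spacing, nsub,
                )
        # 3. growth
        ix = ((colony.x[:n] - origin[0]) / spacing).astype(np.int64)
        iy = ((colony.y[:n] - origin[1]) / spacing).astype(np.int64)
        n_loc = nutrient[ix, iy]
        received = np.zeros(n)
        if chem_by_red is not None:  # green senses red's product
            gm = colony.species[:n] == int(Species.GREEN)
            received[gm] = chem_by_red[ix[gm], iy[gm]]
        if chem_by_green is not None:  # red senses green's product
            rm = colony.species[:n] == int(Species.RED)
            received[rm] = chem_by_green[ix[rm], iy[rm]]
        xi = xi_by_species[colony.species[:n]]
        rate = g * colony.area * (n_loc / (kappa + n_loc)) * (1.0 - xi * received)
        np.clip(rate, 0.0, None, out=rate)
        colony.rod[:n] += rate * dt
        colony.grl[:n] = rate
        # 4. division
        _divide_due(colony, rng_divlen, rng_divang, config.division)
        # 5. mechanics
        _mechanics_step(colony, buf, mobility, dt, config.mech.cap_mode)
        state.time += dt
        if state.time + 1e-12 >= next_snapshot:
            record()
            next_snapshot += config.snapshot_every
    # final state
    if not state.snapshots or state.snapshots[-1].time != state.time:
        rho_all = _density(colony, None, shape, origin, spacing)
        record()
    return state.snapshots, pd.DataFrame(state.metrics_rows)


def _relax_fields(nutrient, chem_g, chem_r, rho_all, rho_g, rho_r, config, dt_lim, spacing,
                  tol: float = 1e-5, max_iters: int = 2000):
    """Iterate the chemical fields toward steady state (quasi-steady option)."""
    for _ in range(max_iters):
        prev = nutrient.copy()
        nutrient_step_inplace(nutrient, rho_all, config.nutrient, dt_lim, spacing)
        delta = float(np.abs(nutrient - prev).max())
        if chem_g is not None:
            prev_g = chem_g.copy()
            chemical_step_inplace(chem_g, rho_g, config.chemical, dt_lim, spacing)
            delta = max(delta, float(np.abs(chem_g - prev_g).max()))
        if chem_r is not None:
            prev_r = chem_r.copy()
            chemical_step_inplace(chem_r, rho_r, config.chemical, dt_lim, spacing)
            delta = max(delta, float(np.abs(chem_r - prev_r).max()))
        if delta < tol * dt_lim:  # time derivative below tol
            break
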