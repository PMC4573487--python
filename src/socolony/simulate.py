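"""Simulation orchestration: seeding, the growth-chemistry-mechanics loop,
interaction wiring, termination, and snapshot/metrics output.

This is the public face of the simulator; the array-based inner loop lives
in :mod:`socolony.engine`.  Within every mechanics step the event order is
fixed: densities are rasterized, the chemical fields are sub-stepped, cells
elongate, threshold cells divide, and contacts are resolved with overdamped
motion.  A run ends when the population reaches ``max_cells`` (30,000 in the
full-scale protocol) or the step budget runs out.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .config import (
    DENSITY_COUNTS,
    SEED_BOX_SIZE,
    InteractionSpec,
    SimulationConfig,
    build_interaction,
    config_from_yaml,
    config_to_yaml,
)
from .engine import run_engine
from .growth import GrowthParams
from .io import Snapshot, read_snapshot, write_snapshot
from .metrics import compute_metrics
from .seeding import make_fixture_colony, seed_random, seed_wellmixed, species_counts

__all__ = [
    "SimulationConfig",
    "InteractionSpec",
    "Snapshot",
    "build_interaction",
    "seed_wellmixed",
    "seed_random",
    "species_counts",
    "make_fixture_colony",
    "run",
    "write_snapshot",
    "read_snapshot",
    "config_to_yaml",
    "config_from_yaml",
    "reduced_scale_config",
    "DENSITY_COUNTS",
    "SEED_BOX_SIZE",
]


def run(config: SimulationConfig, with_metrics: bool = True):
    """Run a colony simulation.

    Returns ``(snapshots, metrics)``: the list of :class:`Snapshot` at the
    configured cadence (always including the final state) and a DataFrame
    time series of the structure metrics (sector counts are computed for the
    final state only, mirroring the full-scale analysis protocol).
    """
    growth = config.growth

    def collect(snapshot: Snapshot) -> dict:
        cells = snapshot.to_cells()
        nutrient = snapshot.fields.get("nutrient") if snapshot.fields else None
        rec = compute_metrics(
            cells, nutrient, growth, time=snapshot.time, spacing=config.grid_spacing
        )
        return dataclasses.asdict(rec)

    snapshots, metrics = run_engine(config, collect_metrics_fn=collect if with_metrics else None)
    if with_metrics and snapshots:
        final = snapshots[-1]
        from .metrics import active_cells, count_sectors

        cells = final.to_cells()
        nutrient = final.fields.get("nutrient") if final.fields else None
        sectors = count_sectors(active_cells(cells, nutrient, growth))
        metrics = metrics.copy()
        metrics.loc[metrics.index[-1], "sectors"] = sectors
    return snapshots, metrics


def reduced_scale_config(
    interaction_type: str,
    seed: int,
    strength: float = 2.0,
    seeding_mode: str = "random",
    density: str = "high",
    ratio: tuple[int, int] = (1, 1),
    max_cells: int = 5000,
) -> SimulationConfig:
    """The desk-scale survey protocol: 5,000-cell colonies in a 300-um box.

    Same physics and parameter set as the full-scale protocol, with the
    domain shrunk to fit the smaller colony, a 1e-3 tau mechanics timestep,
    and contact mobility 2e3.  The mobility keeps the mechanical hierarchy
    of the model — pair relaxation in ~2% of a division time and steady
    overlaps of a few percent of a cell diameter — while keeping the
    displacement-capped integration affordable; colony structure metrics
    are insensitive to it (see docs/methods.md).  The nutrient consumption
    rate is raised to 60/tau so the two dimensionless numbers that shape a
    depleted colony — the depletion strength alpha*rho*R^2/D_n and the
    active-layer-to-radius ratio sqrt(D_n*kappa/(alpha*rho))/R — match the
    full-scale protocol at the smaller final radius; the secreted-chemical
    interaction length (10 um, a few cell lengths) is anchored to the cell
    scale and stays unchanged.  Densities are re-rasterized every 4 steps;
    snapshots every 0.5 tau.
    """
    from .fields import ChemicalParams
    from .mechanics import MechParams

    return SimulationConfig(
        interaction=build_interaction(interaction_type, strength),
        seeding_mode=seeding_mode,
        density=density,
        ratio=ratio,
        mech=MechParams(timestep=1e-3, mobility=2e3),
        nutrient=ChemicalParams(D=3.0e4, alpha_n=60.0, kappa=0.3, beta=0.0),
        domain_size=300.0,
        max_cells=max_cells,
        seed=seed,
        snapshot_every=0.5,
        density_every=4,
        record_fields=True,
    )
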