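"""Snapshot container and plain-text I/O.

A snapshot is a timestamped per-cell state table (one row per cell) plus,
optionally, the chemical/density lattices current at that time.  The on-disk
format is a CSV with a single ``# socolony-snapshot`` comment header carrying
the timestamp, so external segmented data can be fed to the metrics module
by writing the same columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import Cell, Species

__all__ = [
    "Snapshot",
    "SNAPSHOT_COLUMNS",
    "cells_to_frame",
    "frame_to_cells",
    "write_snapshot",
    "read_snapshot",
]

SNAPSHOT_COLUMNS = [
    "id",
    "species",
    "lineage",
    "x",
    "y",
    "angle",
    "rod_length",
    "diameter",
    "division_length",
    "growth_rate_last",
]

_SPECIES_NAMES = {Species.GREEN: "green", Species.RED: "red"}
_SPECIES_VALUES = {"green": Species.GREEN, "red": Species.RED}


@dataclass
class Snapshot:
    """Per-cell state at one instant; ``fields`` maps names to field objects."""

    time: float
    cells: pd.DataFrame
    fields: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_cells(self) -> list[Cell]:
        return frame_to_cells(self.cells)


def cells_to_frame(cells: list[Cell]) -> pd.DataFrame:
    """Tabulate Cell objects into the canonical snapshot columns."""
    return pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "species": [_SPECIES_NAMES[Species(c.species)] for c in cells],
            "lineage": [c.lineage for c in cells],
            "x": [c.center[0] for c in cells],
            "y": [c.center[1] for c in cells],
            "angle": [c.angle for c in cells],
            "rod_length": [c.rod_length for c in cells],
            "diameter": [c.diameter for c in cells],
            "division_length": [c.division_length for c in cells],
            "growth_rate_last": [c.growth_rate_last for c in cells],
        }
    )


def frame_to_cells(frame: pd.DataFrame) -> list[Cell]:
    cells = []
    for row in frame.itertuples(index=False):
        cells.append(
            Cell(
                id=int(row.id),
                species=_SPECIES_VALUES[row.species],
                lineage=int(row.lineage),
                center=np.array([row.x, row.y]),
                angle=float(row.angle),
                rod_length=float(row.rod_length),
                diameter=float(row.diameter),
                division_length=float(row.division_length),
                growth_rate_last=float(row.growth_rate_last),
            )
        )
    return cells


def write_snapshot(snapshot: Snapshot, path) -> None:
    """Write a snapshot as CSV with a one-line timestamp header."""
    with open(path, "w") as fh:
        fh.write(f"# socolony-snapshot time={snapshot.time!r}\n")
        snapshot.cells.to_csv(fh, index=False, columns=SNAPSHOT_COLUMNS)


def read_snapshot(path) -> Snapshot:
    """Read a snapshot written by :func:`write_snapshot`.

    Malformed files raise ValueError naming the offending line.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("# socolony-snapshot time="):
        raise ValueError(f"{path}: line 1: missing '# socolony-snapshot time=' header")
    try:
        time = float(lines[0].split("time=", 1)[1])
    except ValueError as exc:
        raise ValueError(f"{path}: line 1: unreadable timestamp") from exc
    if len(lines) < 2:
        raise ValueError(f"{path}: line 2: missing column header")
    header = [h.strip() for h in lines[1].strip().split(",")]
    missing = [c for c in SNAPSHOT_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: line 2: missing columns {missing}")
    rows = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.strip().split(",")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        rec = dict(zip(header, parts))
        try:
            rows.append(
                {
                    "id": int(rec["id"]),
                    "species": rec["species"],
                    "lineage": int(rec["lineage"]),
                    "x": float(rec["x"]),
                    "y": float(rec["y"]),
                    "angle": float(rec["angle"]),
                    "rod_length": float(rec["rod_length"]),
                    "diameter": float(rec["diameter"]),
                    "division_length": float(rec["division_length"]),
                    "growth_rate_last": float(rec["growth_rate_last"]),
                }
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        if rows[-1]["species"] not in _SPECIES_VALUES:
            raise ValueError(f"{path}: line {lineno}: unknown species {rec['species']!r}")
    frame = pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)
    if not frame.empty and frame["id"].duplicated().any():
        dup = int(frame.loc[frame["id"].duplicated(), "id"].iloc[0])
        raise ValueError(f"{path}: duplicate cell id {dup}")
    if frame.empty:
        frame = frame.astype(
            {
                "id": np.int64,
                "lineage": np.int64,
                "x": float,
                "y": float,
                "angle": float,
                "rod_length": float,
                "diameter": float,
                "division_length": float,
                "growth_rate_last": float,
            },
            errors="ignore",
        )
    return Snapshot(time=time, cells=frame)
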