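"""Run configuration: interaction wirings and full simulation parameterization.

The six pairwise social interactions are wired through at most two secreted
chemicals, one per producing species.  A species only senses the chemical
produced by the *other* species; ``xi_green`` is the signed strength with
which green responds to red's chemical (positive = toxin, negative = public
good), and symmetrically for ``xi_red``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .fields import ChemicalParams, DEFAULT_SPACING
from .growth import DivisionRule, GrowthParams
from .mechanics import MechParams

__all__ = [
    "InteractionSpec",
    "build_interaction",
    "SimulationConfig",
    "config_to_yaml",
    "config_from_yaml",
    "INTERACTION_TYPES",
    "DENSITY_COUNTS",
    "SEED_BOX_SIZE",
]

INTERACTION_TYPES = (
    "control",
    "commensalism",
    "amensalism",
    "competition",
    "mutualism",
    "parasitism",
)

#: Initial cell counts for the three seeding densities (60x60 um^2 square).
DENSITY_COUNTS = {"high": 256, "medium": 64, "low": 16}

#: Side length (um) of the square in which initial cells are seeded.
SEED_BOX_SIZE = 60.0


@dataclass
class InteractionSpec:
    """One of the six pairwise social interaction wirings."""

    type: str
    produces_green: bool = False
    produces_red: bool = False
    xi_green: float = 0.0  # strength green feels from red's chemical
    xi_red: float = 0.0  # strength red feels from green's chemical

    def __post_init__(self) -> None:
        if self.type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.type!r}")


def build_interaction(
    type: str, strength: float = 2.0, parasitism_one_chemical: bool = False
) -> InteractionSpec:
    """Standard wiring for an interaction type with magnitude ``strength``.

    The default magnitude is calibrated against the produced-chemical scale
    (c ~ rho/beta ~ 0.5-1 near dense fronts, ~1.2 in packed cores): at
    |xi| = 2 a toxin shuts growth down where the producing species is locally
    dense, without acting instantaneously at the dilute front — which is the
    regime in which the six interactions produce qualitatively distinct
    colony structures (victim species marginalized under amensalism,
    sector-boundary pinning under competition, growth boosts up to ~3x in
    well-mixed mutualistic regions).

    Asymmetric types follow the convention that red is the producer and green
    the receiver (commensalism: green benefits; amensalism: green is harmed),
    and parasitism has green as the beneficiary: red secretes a public good
    for green while green secretes a toxin against red.  With
    ``parasitism_one_chemical`` only the toxin against red is kept.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    s = float(strength)
    if type == "control":
        return InteractionSpec("control")
    if type == "commensalism":
        return InteractionSpec("commensalism", False, True, xi_green=-s)
    if type == "amensalism":
        return InteractionSpec("amensalism", False, True, xi_green=+s)
    if type == "competition":
        return InteractionSpec("competition", True, True, xi_green=+s, xi_red=+s)
    if type == "mutualism":
        return InteractionSpec("mutualism", True, True, xi_green=-s, xi_red=-s)
    if type == "parasitism":
        if parasitism_one_chemical:
            return InteractionSpec("parasitism", True, False, xi_red=+s)
        return InteractionSpec("parasitism", True, True, xi_green=-s, xi_red=+s)
    raise ValueError(f"unknown interaction type {type!r}")


@dataclass
class SimulationConfig:
    """Full parameterization of a colony run.

    ``density`` is one of 'high'/'medium'/'low' (256/64/16 seed cells);
    ``ratio`` the green:red abundance pair.  ``timestep`` lives in ``mech``;
    chemistry is sub-stepped automatically to satisfy the FTCS stability
    bound.  The run exits once the population reaches ``max_cells``.
    """

    interaction: InteractionSpec = field(default_factory=lambda: build_interaction("control"))
    seeding_mode: str = "wellmixed"  # "wellmixed" | "random"
    density: str = "high"
    ratio: tuple[int, int] = (1, 1)
    mech: MechParams = field(default_factory=MechParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    division: DivisionRule = field(default_factory=DivisionRule)
    nutrient: ChemicalParams = field(default_factory=ChemicalParams.nutrient_defaults)
    chemical: ChemicalParams = field(default_factory=ChemicalParams.chemical_defaults)
    domain_size: float = 1000.0
    grid_spacing: float = DEFAULT_SPACING
    max_cells: int = 30000
    max_steps: int = 5_000_000
    seed: int = 0
    swap_species: bool = False  # relabel green<->red after seeding (symmetry checks)
    snapshot_every: float = 0.5  # tau between snapshots
    density_every: int = 1  # mechanics steps between density re-rasterizations
    quasi_steady_chem: bool = False
    record_fields: bool = True

    def __post_init__(self) -> None:
        if self.seeding_mode not in ("wellmixed", "random"):
            raise ValueError("seeding_mode must be 'wellmixed' or 'random'")
        if self.density not in DENSITY_COUNTS:
            raise ValueError("density must be one of 'high', 'medium', 'low'")
        self.ratio = (int(self.ratio[0]), int(self.ratio[1]))
        if min(self.ratio) <= 0:
            raise ValueError("ratio entries must be positive")
        if self.max_cells < DENSITY_COUNTS[self.density]:
            raise ValueError("max_cells must be >= the initial cell count")

    @property
    def n_initial(self) -> int:
        return DENSITY_COUNTS[self.density]


def config_to_yaml(config: SimulationConfig, path=None) -> str:
    """Serialize a config (full parameter echo) to YAML."""
    data = asdict(config)
    data["ratio"] = list(config.ratio)
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _subconfig(cls, data: dict[str, Any] | None):
    return cls(**data) if data else cls()


def config_from_yaml(source) -> SimulationConfig:
    """Load a config from a YAML string or file path."""
    text = source
    if isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
        with open(source) as fh:
            text = fh.read()
    data = yaml.safe_load(text) or {}
    kwargs: dict[str, Any] = {}
    for key, cls in (
        ("interaction", InteractionSpec),
        ("mech", MechParams),
        ("growth", GrowthParams),
        ("division", DivisionRule),
        ("nutrient", ChemicalParams),
        ("chemical", ChemicalParams),
    ):
        if key in data:
            kwargs[key] = _subconfig(cls, data.pop(key))
    if "ratio" in data:
        data["ratio"] = tuple(data["ratio"])
    kwargs.update(data)
    return SimulationConfig(**kwargs)
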