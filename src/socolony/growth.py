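"""Cell growth and division.

Elongation follows Monod kinetics in the local nutrient concentration,
scaled by cell area and modulated linearly by a received social chemical
(toxin or public good): dl/dt = g * A * n/(kappa+n) * (1 - xi*T), clamped at
zero so strong toxins stop growth rather than shrink cells.  A cell divides
once its total (cap-to-cap) length reaches its personal division threshold,
drawn at birth from a normal distribution with mean 4.0 um and s.d. 0.3 um
clipped to [3.1, 4.9] um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .mechanics import Cell

__all__ = [
    "GrowthParams",
    "DivisionRule",
    "elongation_rate",
    "elongate",
    "sample_division_length",
    "maybe_divide",
]


@dataclass
class GrowthParams:
    """Growth parameters.

    g is the per-area elongation rate constant (um^-1 tau^-1 per unit area,
    tau = 30 min), sized so an unimpeded cell divides in roughly one tau;
    kappa is the Monod half-saturation in (boundary-scaled) nutrient units;
    xi is the signed interaction strength toward the received chemical
    (positive = toxin, negative = public good).
    """

    g: float = 0.5
    kappa: float = 0.3
    xi: float = 0.0

    def __post_init__(self) -> None:
        if self.g <= 0 or self.kappa <= 0:
            raise ValueError("g and kappa must be > 0")


@dataclass
class DivisionRule:
    """Truncated-normal division length (um), clipped to [lower, upper].

    ``threshold_on`` selects whether the threshold applies to the cell's
    total (cap-to-cap) length (default) or to the bare rod length.
    """

    mean: float = 4.0
    sd: float = 0.3
    lower: float = 3.1
    upper: float = 4.9
    threshold_on: str = "total"  # "total" | "rod"
    angle_noise: float = 0.05  # uniform +/- rad applied to each daughter

    def __post_init__(self) -> None:
        if not (self.lower < self.mean < self.upper):
            raise ValueError("need lower < mean < upper")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.threshold_on not in ("total", "rod"):
            raise ValueError("threshold_on must be 'total' or 'rod'")


def elongation_rate(
    cell: Cell,
    n_local: float,
    t_local: float | np.ndarray,
    params: GrowthParams,
) -> float:
    """Length growth rate (um per tau), never negative.

    ``t_local`` may be a scalar received-chemical concentration (paired with
    scalar ``params.xi``) or an array of concentrations paired with an array
    of strengths, combined additively as 1 - sum(xi_c * T_c).
    """
    monod = n_local / (params.kappa + n_local)
    social = 1.0 - float(np.sum(np.asarray(params.xi) * np.asarray(t_local)))
    return max(0.0, params.g * cell.area * monod * social)


def elongate(cell: Cell, rate: float, dt: float) -> Cell:
    """Advance rod length by rate*dt; records the rate in growth_rate_last."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    out = cell.copy()
    out.rod_length = cell.rod_length + rate * dt
    out.growth_rate_last = rate
    return out


def sample_division_length(rule: DivisionRule, rng: np.random.Generator) -> float:
    """One clipped-normal division-length draw (um)."""
    return float(min(max(rng.normal(rule.mean, rule.sd), rule.lower), rule.upper))


def maybe_divide(
    cell: Cell,
    rule: DivisionRule,
    rng: np.random.Generator,
    next_id: int | None = None,
) -> list[Cell]:
    """Split the cell in two once it reaches its division threshold.

    Daughters inherit species and lineage, receive fresh ids and fresh
    division-length draws, and are placed symmetrically along the parent
    axis so their spherocylinders exactly tile the parent's footprint:
    daughter rod length (L_rod - d)/2, centers offset by +/- (l_d + d)/2.
    A small uniform angular perturbation (rule.angle_noise) breaks perfect
    collinearity.  Returns [cell] (unchanged) below threshold.
    """
    measured = cell.total_length if rule.threshold_on == "total" else cell.rod_length
    if measured < cell.division_length:
        return [cell]
    d = cell.diameter
    child_rod = max(0.0, (cell.rod_length - d) / 2.0)
    offset = (child_rod + d) / 2.0
    axis = cell.axis
    base = cell.id if next_id is None else next_id
    daughters = []
    for k, sign in enumerate((-1.0, 1.0)):
        noise = rng.uniform(-rule.angle_noise, rule.angle_noise) if rule.angle_noise else 0.0
        daughters.append(
            Cell(
                id=base + k,
                species=cell.species,
                lineage=cell.lineage,
                center=cell.center + sign * offset * axis,
                angle=(cell.angle + noise) % (2.0 * math.pi),
                rod_length=child_rod,
                diameter=d,
                division_length=sample_division_length(rule, rng),
                growth_rate_last=cell.growth_rate_last,
            )
        )
    return daughters
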