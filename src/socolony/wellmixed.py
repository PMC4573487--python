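"""Two-species well-mixed batch-growth model.

A shared nutrient n drives Monod growth of two species u and v; each
species' growth is additionally scaled by a linear factor in the *other*
species' density, standing in for a secreted toxin or public good at
production-degradation steady state:

    du/dt = alpha * n/(kappa+n) * (1 - xi1 * v) * u
    dv/dt = alpha * n/(kappa+n) * (1 - xi2 * u) * v
    dn/dt = -yield * alpha * n/(kappa+n) * (u + v)

Positive xi is a toxin, negative a public good.  By default the (1 - xi*rho)
factor may go negative, modeling net death under a strong toxin; this is
what produces competitive exclusion in a batch culture (``clamp_growth``
restores the growth-only behavior of the spatial model).  Densities are
floored at zero.  The nutrient holds a finite budget, so outcomes are read
at nutrient exhaustion; the default initial nutrient (50 in units of the
initial-biomass scale) supplies enough total growth for the qualitative
outcomes — mutualistic convergence to 1:1, bistable competitive exclusion,
parasitic takeover — to complete before the batch starves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "OdeState",
    "OdeParams",
    "rhs",
    "integrate",
    "classify_outcome",
    "ensemble_final_fraction",
    "phase_scan",
    "DEFAULT_N0",
    "OUTCOMES",
]

DEFAULT_N0 = 50.0
OUTCOMES = ("coexistence", "bistable_exclusion", "dominance_u", "dominance_v", "neutral_line")

#: Default initial conditions for outcome classification: total biomass 0.01
#: split at ratios on both sides of the u = v diagonal.
DEFAULT_RATIOS = ((1, 7), (1, 3), (3, 1), (7, 1))


@dataclass
class OdeState:
    n: float
    u: float
    v: float

    def __post_init__(self) -> None:
        if min(self.n, self.u, self.v) < 0:
            raise ValueError("state components must be >= 0")


@dataclass
class OdeParams:
    alpha: float = 1.0
    kappa: float = 0.3
    xi1: float = 0.0  # strength of v's effect on u (positive = toxin)
    xi2: float = 0.0  # strength of u's effect on v
    yield_: float = 1.0  # nutrient consumed per unit biomass grown
    clamp_growth: bool = False  # clamp (1 - xi*rho) at 0 instead of allowing death

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.kappa <= 0:
            raise ValueError("alpha and kappa must be > 0")


def rhs(state: OdeState, params: OdeParams) -> tuple[float, float, float]:
    """(dn/dt, du/dt, dv/dt) at a state; densities floored at zero."""
    n = max(state.n, 0.0)
    u = max(state.u, 0.0)
    v = max(state.v, 0.0)
    monod = params.alpha * n / (params.kappa + n)
    fu = 1.0 - params.xi1 * v
    fv = 1.0 - params.xi2 * u
    if params.clamp_growth:
        fu = max(fu, 0.0)
        fv = max(fv, 0.0)
    return (
        -params.yield_ * monod * (u + v),
        monod * fu * u,
        monod * fv * v,
    )


def integrate(
    state0: OdeState,
    params: OdeParams,
    t_end: float = 5000.0,
    rtol: float = 1e-10,
    atol: float = 1e-16,
    n_quiescent: float = 1e-6,
) -> pd.DataFrame:
    """Integrate to ``t_end`` or quiescence (nutrient below ``n_quiescent``).

    Adaptive integration (LSODA); returns the trajectory as a DataFrame with
    columns t, n, u, v.
    """

    def f(t, y):
        return rhs(OdeState(max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0)), params)

    def exhausted(t, y):
        return y[0] - n_quiescent

    exhausted.terminal = True
    exhausted.direction = -1

    sol = solve_ivp(
        f,
        (0.0, t_end),
        [state0.n, state0.u, state0.v],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=exhausted,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    return pd.DataFrame({"t": sol.t, "n": y[0], "u": y[1], "v": y[2]})


def _final(state0, params, **kw):
    traj = integrate(state0, params, **kw)
    return float(traj.u.iloc[-1]), float(traj.v.iloc[-1])


def classify_outcome(
    params: OdeParams,
    initial_conditions=None,
    n0: float = DEFAULT_N0,
    total: float = 0.01,
    survival_eps_rel: float = 1e-6,
    coexist_spread: float = 0.02,
) -> str:
    """Phase-diagram outcome over a set of initial conditions.

    Integrates each initial condition to quiescence and inspects which
    species end above the survival threshold (1e-6 of the initial biomass):
    a single survivor in all runs gives dominance; a run-dependent winner is
    bistable exclusion; joint survival is coexistence when the final green
    fraction is insensitive to the initial condition and the neutral line
    otherwise.
    """
    if initial_conditions is None:
        initial_conditions = [
            OdeState(n0, total * a / (a + b), total * b / (a + b)) for a, b in DEFAULT_RATIOS
        ]
    survivors = []
    fracs = []
    for ic in initial_conditions:
        eps = survival_eps_rel * (ic.u + ic.v)
        u_end, v_end = _final(ic, params)
        survivors.append((u_end > eps, v_end > eps))
        tot_end = u_end + v_end
        fracs.append(u_end / tot_end if tot_end > 0 else 0.5)
    if all(su and sv for su, sv in survivors):
        return "coexistence" if max(fracs) - min(fracs) < coexist_spread else "neutral_line"
    if all(su and not sv for su, sv in survivors):
        return "dominance_u"
    if all(sv and not su for su, sv in survivors):
        return "dominance_v"
    return "bistable_exclusion"


def ensemble_final_fraction(
    params: OdeParams,
    n_draws: int,
    rng: np.random.Generator,
    n0: float = DEFAULT_N0,
    total: float = 0.01,
):
    """Mean and variance of the final green fraction over random (u0, v0).

    Initial fractions are uniform on (0, 1) at fixed total biomass.
    Returns (mean, variance, fractions array).
    """
    if n_draws < 2:
        raise ValueError("need n_draws >= 2")
    fracs = np.empty(n_draws)
    for k in range(n_draws):
        f0 = rng.uniform(0.0, 1.0)
        u_end, v_end = _final(OdeState(n0, total * f0, total * (1.0 - f0)), params)
        tot = u_end + v_end
        fracs[k] = u_end / tot if tot > 0 else 0.5
    return float(fracs.mean()), float(fracs.var()), fracs


def phase_scan(
    xi1_values,
    xi2_values,
    params: OdeParams | None = None,
    **classify_kw,
) -> np.ndarray:
    """Outcome label for each (xi1, xi2) grid point (object array of str)."""
    base = params or OdeParams()
    out = np.empty((len(xi1_values), len(xi2_values)), dtype=object)
    for i, x1 in enumerate(xi1_values):
        for j, x2 in enumerate(xi2_values):
            p = OdeParams(
                alpha=base.alpha, kappa=base.kappa, xi1=float(x1), xi2=float(x2),
                yield_=base.yield_, clamp_growth=base.clamp_growth,
            )
            out[i, j] = classify_outcome(p, **classify_kw)
    return out
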