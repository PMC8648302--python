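"""Enzyme-limited C4 photosynthesis model and the slope-conductance relation.

The C4 pathway concentrates CO2 by fixing it first in the mesophyll cytosol
(PEP carboxylase, PEPC) and releasing it in the bundle sheath where Rubisco
operates.  At low intercellular CO2 the net assimilation rate A is limited by
PEPC and by the supply of CO2 across the mesophyll plasma membrane, so the
initial slope of the A-Ci curve carries information about the mesophyll
conductance g_m (mol m-2 s-1 bar-1).  Combining the linearised PEPC response
(V_pmax/K_p) in series with the diffusive conductance gives the closed form

    dA/dCi = g_m * V_pmax / (g_m * K_p + V_pmax)

which this module provides together with its algebraic inverse, the full
enzyme-limited forward model A(Cm), and the coupled diffusion/biochemistry
solution A(Ci, g_m).

Units package-wide: A in umol m-2 s-1, partial pressures in ubar, conductances
and slopes in mol m-2 s-1 bar-1 (numerically equal to umol m-2 s-1 ubar-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError

__all__ = [
    "C4ModelParams",
    "DEFAULT_PARAMS",
    "initial_slope_from_gm",
    "gm_from_initial_slope",
    "enzyme_limited_assimilation",
    "solve_A_from_Ci",
    "predicted_slope_curve",
]


@dataclass(frozen=True)
class C4ModelParams:
    """Kinetic constants of the enzyme-limited C4 model.

    Attributes
    ----------
    Vpmax : float
        Maximal PEP-carboxylase activity, umol m-2 s-1.
    Kp : float
        Michaelis constant of PEPC for CO2, ubar.
    Vpr : float
        PEP-regeneration-limited cap on the carboxylation rate, umol m-2 s-1.
    Vcmax : float
        Maximal Rubisco carboxylation rate in the bundle sheath, umol m-2 s-1.
    gbs : float
        Bundle-sheath conductance to CO2 leakage, mol m-2 s-1 bar-1.
    Rd : float
        Day respiration, umol m-2 s-1.
    Rm : float
        Mesophyll fraction of day respiration, umol m-2 s-1 (Rm <= Rd).

    The defaults pin Vpmax and Kp to the values used for the slope relation
    (250 umol m-2 s-1 and 82 ubar); the remaining constants follow the
    standard C4 model literature, with Vcmax chosen so the saturating
    assimilation rate is ~41 umol m-2 s-1, typical of young Setaria leaves.
    """

    Vpmax: float = 250.0
    Kp: float = 82.0
    Vpr: float = 80.0
    Vcmax: float = 42.0
    gbs: float = 3e-3
    Rd: float = 1.0
    Rm: float = 0.5

    def __post_init__(self) -> None:
        for name in ("Vpmax", "Kp", "Vpr", "Vcmax", "gbs"):
            if not getattr(self, name) > 0:
                raise DomainError(f"C4ModelParams.{name} must be strictly positive")
        if self.Rd < 0 or self.Rm < 0:
            raise DomainError("Rd and Rm must be non-negative")
        if self.Rm > self.Rd:
            raise DomainError("Rm cannot exceed Rd")

    def replace(self, **kwargs) -> "C4ModelParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


DEFAULT_PARAMS = C4ModelParams()


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        if not (math.isfinite(v) and v > 0):
            raise DomainError(f"{name} must be finite and strictly positive, got {v!r}")


def initial_slope_from_gm(gm: float, Vpmax: float = 250.0, Kp: float = 82.0) -> float:
    """Initial slope dA/dCi of the A-Ci curve for mesophyll conductance ``gm``.

    Series combination of the diffusive conductance g_m and the linearised
    PEPC carboxylation efficiency V_pmax/K_p:

        dA/dCi = gm * Vpmax / (gm * Kp + Vpmax)

    Parameters are in package units (gm in mol m-2 s-1 bar-1, Vpmax in
    umol m-2 s-1, Kp in ubar); the slope comes out in mol m-2 s-1 bar-1.
    """
    _check_positive(gm=gm, Vpmax=Vpmax, Kp=Kp)
    return gm * Vpmax / (gm * Kp + Vpmax)


def gm_from_initial_slope(slope: float, Vpmax: float = 250.0, Kp: float = 82.0) -> float:
    """Invert the slope relation: the g_m that produces a given initial slope.

    Defined for 0 < slope < Vpmax/Kp (the PEPC-limited asymptote); exact
    algebraic inverse of :func:`initial_slope_from_gm`.
    """
    _check_positive(slope=slope, Vpmax=Vpmax, Kp=Kp)
    asymptote = Vpmax / Kp
    if slope >= asymptote:
        raise DomainError(
            f"slope {slope} exceeds PEPC-limited asymptote Vpmax/Kp = {asymptote:.4f}"
        )
    return slope * Vpmax / (Vpmax - slope * Kp)


def enzyme_limited_assimilation(Cm: float, params: C4ModelParams = DEFAULT_PARAMS) -> float:
    """Net assimilation A (umol m-2 s-1) at mesophyll CO2 partial pressure Cm.

    Simplified enzyme-limited C4 model with a CO2-saturated bundle sheath:

        Vp = min(Cm * Vpmax / (Cm + Kp), Vpr)
        A  = min(Vp + gbs * Cm - Rm,  Vcmax - Rd)

    The first branch is PEPC/PEP-regeneration limitation (plus direct CO2
    leak-in through the bundle-sheath conductance), the second Rubisco
    limitation once the CO2 pump saturates.  Oxygen terms are omitted: the
    bundle sheath is treated as CO2-saturated, appropriate for the low-O2
    regime the slope analysis targets.
    """
    if not math.isfinite(Cm) or Cm < 0:
        raise DomainError(f"Cm must be finite and non-negative, got {Cm!r}")
    vp = min(Cm * params.Vpmax / (Cm + params.Kp), params.Vpr)
    return min(vp + params.gbs * Cm - params.Rm, params.Vcmax - params.Rd)


def solve_A_from_Ci(
    Ci: float,
    gm: float,
    params: C4ModelParams = DEFAULT_PARAMS,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """Solve the coupled diffusion/biochemistry balance at intercellular CO2 Ci.

    Finds the mesophyll CO2 partial pressure Cm at which the diffusive supply
    equals the biochemical demand,

        gm * (Ci - Cm) = A(Cm),

    and returns ``(A, Cm)``.  Bracketed scalar root-finding on
    Cm in [0, Ci + margin]; converged to |residual| < ``tol`` umol m-2 s-1.
    """
    if not math.isfinite(Ci) or Ci < 0:
        raise DomainError(f"Ci must be finite and non-negative, got {Ci!r}")
    _check_positive(gm=gm)

    def f(cm: float) -> float:
        return gm * (Ci - cm) - enzyme_limited_assimilation(cm, params)

    lo, hi = 0.0, Ci + (params.Rd + 1.0) / gm + 1.0
    flo = f(lo)
    if flo <= 0.0:
        # demand already balances supply at Cm = 0 (only when both vanish)
        cm = 0.0
    else:
        try:
            cm = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
        except ValueError as exc:  # pragma: no cover - bracket is constructed valid
            raise ConvergenceError(
                f"no sign change on Cm bracket [0, {hi:.3f}] at Ci={Ci}, gm={gm}: {exc}"
            ) from exc
    A = gm * (Ci - cm)
    resid = A - enzyme_limited_assimilation(cm, params)
    # at very large gm the residual in A is limited by machine precision of Cm
    tol = max(tol, (gm + params.Vpmax / params.Kp) * max(Ci, 1.0) * 1e-14)
    if abs(resid) > tol:
        raise ConvergenceError(
            f"solver residual {resid:.3e} exceeds {tol:.1e} at Ci={Ci}, gm={gm}, Cm={cm}"
        )
    return A, cm


def predicted_slope_curve(
    gm_grid, Vpmax: float = 250.0, Kp: float = 82.0
) -> list[tuple[float, float]]:
    """Model-predicted initial slope at each conductance of a sorted grid.

    Returns ``[(gm, slope), ...]`` — the curve against which measured
    (slope, g_m) pairs are compared.
    """
    grid = list(gm_grid)
    if not grid:
        raise DomainError("gm_grid must be non-empty")
    if any(g2 <= g1 for g1, g2 in zip(grid, grid[1:])):
        raise DomainError("gm_grid must be strictly increasing")
    return [(g, initial_slope_from_gm(g, Vpmax, Kp)) for g in grid]
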