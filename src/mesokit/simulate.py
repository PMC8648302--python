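"""Forward simulators for every record type the estimators consume.

Each generator is the documented inverse of its estimator: under zero noise,
feeding generated records back through the corresponding fit recovers the
generating parameters to solver tolerance.  Defaults reproduce the study
conditions (2% O2, 380 umol mol-1 reference CO2, 25 C leaf temperature,
1500 umol m-2 s-1 irradiance, 55% relative humidity; 10 isotope readings per
leaf; 0.2 s stopped-flow acquisition; 10-min plate-reader sampling over
24-30 h).

All randomness derives from one integer seed; each record type draws from a
deterministic substream so generating one data type never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .aci import ACiCurve, GasExchangeRecord
from .c4model import C4ModelParams, DEFAULT_PARAMS, solve_A_from_Ci
from .errors import DomainError
from .growth import GrowthCurve
from .isoflux import (
    DEFAULT_CONSTANTS,
    FractionationConstants,
    IsotopeExchangeRecord,
    equilibrated_source_delta,
    liquid_water_from_vapor,
    vsmow_to_co2_scale,
)
from .permeability import CellGeometry, StoppedFlowTrace, surface_to_volume

__all__ = [
    "SimulationConfig",
    "DEFAULT_ACI_GRID_PPM",
    "gen_aci",
    "gen_isotope_records",
    "gen_stopped_flow",
    "gen_growth_curves",
]

_CHANNELS = {"aci": 11, "isotope": 23, "stopped_flow": 37, "growth": 53}

#: default Ca setpoints, ppm, emulating a stepwise 0-1600 ppm response
DEFAULT_ACI_GRID_PPM = (
    0, 25, 50, 75, 100, 125, 150, 175, 200, 250, 300, 380,
    500, 650, 800, 1000, 1200, 1400, 1600,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Seed, per-channel noise levels, and environmental conditions.

    Noise: sigma_A on assimilation (umol m-2 s-1), sigma_delta on CO2 deltas
    (per mil), sigma_delta_vapor on vapor deltas (per mil), sigma_F fractional
    multiplicative fluorescence noise, sigma_od additive OD noise.
    """

    seed: int = 0
    sigma_A: float = 0.2
    sigma_delta: float = 0.3
    sigma_delta_vapor: float = 0.1
    sigma_F: float = 0.01
    sigma_od: float = 0.003
    Tleaf: float = 25.0
    Patm: float = 1.0
    o2_percent: float = 2.0
    co2_ref_ppm: float = 380.0
    rh_percent: float = 55.0
    irradiance: float = 1500.0
    gsw: float = 0.3
    flow_umol_s: float = 150.0
    leaf_area_m2: float = 6e-4

    def __post_init__(self) -> None:
        for name in ("sigma_A", "sigma_delta", "sigma_delta_vapor", "sigma_F", "sigma_od"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if not self.Patm > 0 or not self.gsw > 0:
            raise DomainError("Patm and gsw must be positive")

    def rng(self, channel: str) -> np.random.Generator:
        """Deterministic substream for one record type."""
        return np.random.default_rng(
            np.random.SeedSequence((int(self.seed), _CHANNELS[channel]))
        )

    def transpiration(self) -> float:
        """Steady-state transpiration E (mol m-2 s-1) from gsw, Tleaf, RH.

        Tetens saturation vapor pressure; chamber air at the configured
        relative humidity, leaf intercellular air saturated at Tleaf.
        """
        es_kpa = 0.6108 * math.exp(17.27 * self.Tleaf / (self.Tleaf + 237.3))
        wi = es_kpa / (self.Patm * 100.0)
        wa = wi * self.rh_percent / 100.0
        return self.gsw * (wi - wa)


def _solve_operating_point(
    ca_ubar: float, gm: float, gsw: float, params: C4ModelParams
) -> tuple[float, float, float]:
    """Steady-state (A, Ci, Cm) for a leaf at ambient Ca with constant gsw.

    Stomatal CO2 conductance gsc = gsw/1.6 couples Ca to Ci; the mesophyll
    solution comes from :func:`solve_A_from_Ci`.
    """
    gsc = gsw / 1.6

    def f(ci: float) -> float:
        a, _ = solve_A_from_Ci(ci, gm, params)
        return gsc * (ca_ubar - ci) - a

    lo = 0.0
    hi = ca_ubar + (params.Rd + 1.0) / gsc + 1.0
    if f(lo) <= 0.0:
        ci = 0.0
    else:
        ci = brentq(f, lo, hi, xtol=1e-12, maxiter=200)
    a, cm = solve_A_from_Ci(ci, gm, params)
    return a, ci, cm


def gen_aci(
    gm: float,
    params: C4ModelParams = DEFAULT_PARAMS,
    ca_grid_ppm=DEFAULT_ACI_GRID_PPM,
    cfg: SimulationConfig = SimulationConfig(),
    genotype: str = "synthetic",
    replicate_id: str = "sim-1",
) -> ACiCurve:
    """Simulate an A-Ci curve for a leaf of known mesophyll conductance.

    For each Ca setpoint the steady-state Ci is found under a constant-gsw
    stomatal rule (stomatal conductance did not differ between genotypes in
    the system this emulates), A is solved from the coupled model, and
    Gaussian noise sigma_A is added to A.
    """
    if not gm > 0:
        raise DomainError("gm must be strictly positive")
    grid = list(ca_grid_ppm)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise DomainError("ca_grid_ppm must be strictly increasing")
    rng = cfg.rng("aci")
    records = []
    for ca_ppm in grid:
        ca = ca_ppm * cfg.Patm
        a, ci, _ = _solve_operating_point(ca, gm, cfg.gsw, params)
        a_noisy = a + rng.normal(0.0, cfg.sigma_A) if cfg.sigma_A > 0 else a
        records.append(
            GasExchangeRecord(
                Ca=ca, Ci=ci, A=a_noisy, gsw=cfg.gsw, Tleaf=cfg.Tleaf, Patm=cfg.Patm
            )
        )
    return ACiCurve(records, genotype=genotype, replicate_id=replicate_id)


def gen_isotope_records(
    gm_true: float,
    theta_mode: str = "full_equilibrium",
    kCA: float | None = None,
    water_delta: float = -8.0,
    n_readings: int = 10,
    cfg: SimulationConfig = SimulationConfig(),
    params: C4ModelParams = DEFAULT_PARAMS,
    consts: FractionationConstants = DEFAULT_CONSTANTS,
    delta_e_co2: float = -30.0,
) -> list[IsotopeExchangeRecord]:
    """Simulate an open-chamber C18O16O measurement batch.

    The leaf operates at the configured ambient conditions; its physical CO2
    drawdown follows ``gm_true``.  The isotopic exchange signal is placed at

    * ``full_equilibrium`` — the true mesophyll CO2 pressure (CA fast), or
    * ``finite_kCA`` — the apparent pressure of a partially equilibrating
      pool, using the effective conductance 1/(1/gm + 3/kCA); equilibrium-mode
      inversion of such data underestimates gm, the CA-limited mode recovers
      it.

    ``water_delta`` is the delta-18O of chamber water vapor (per mil VSMOW);
    ``delta_e_co2`` that of the inlet CO2 on the instrument (VPDB-CO2) scale,
    defaulting to -30 per mil, typical of depleted cylinder CO2 - the
    depletion of supply CO2 relative to leaf-water-equilibrated CO2 is what
    makes the retro-diffusion signal positive.  Per-reading Gaussian noise is
    added to the outlet CO2 delta (sigma_delta), the vapor deltas
    (sigma_delta_vapor) and A (sigma_A); the inlet CO2 delta is a calibrated
    reference and carries no per-reading noise.
    """
    if not gm_true > 0:
        raise DomainError("gm_true must be strictly positive")
    if theta_mode not in ("full_equilibrium", "finite_kCA"):
        raise DomainError(f"unknown theta_mode {theta_mode!r}")
    if theta_mode == "finite_kCA":
        if kCA is None or not kCA > 0:
            raise DomainError("finite_kCA mode requires a positive kCA")
        gm_eff = 1.0 / (1.0 / gm_true + 3.0 / kCA)
    else:
        gm_eff = gm_true
    if n_readings < 1:
        raise DomainError("n_readings must be >= 1")

    ca_leaf = cfg.co2_ref_ppm * cfg.Patm  # ubar, chamber (dry) basis
    a_op, ci_op, _ = _solve_operating_point(ca_leaf, gm_true, cfg.gsw, params)
    cm_iso = ci_op - a_op / gm_eff
    if cm_iso <= 0:
        raise DomainError(
            f"infeasible operating point: isotopic exchange Cm = {cm_iso:.2f} ubar <= 0 "
            f"(A = {a_op:.2f}, Ci = {ci_op:.2f}, effective gm = {gm_eff:.3f})"
        )

    # dry-air chamber mass balance; the chamber (outlet) sits at the reference
    # CO2 mole fraction and the inlet is higher by the leaf's uptake
    s, u = cfg.leaf_area_m2, cfg.flow_umol_s
    co_dry = cfg.co2_ref_ppm
    ce = co_dry + a_op * s * 1e6 / u
    e_leaf = cfg.transpiration()
    dilution = 1.0 + e_leaf * s * 1e6 / u
    co_wet = co_dry / dilution
    xi = ce / (ce - co_dry)

    # self-consistent outlet CO2 delta: Delta_ea depends on delta_o which
    # depends on Delta_obs; fixed-point iteration converges in a few steps
    d_water_liquid = liquid_water_from_vapor(water_delta, cfg.Tleaf)
    d_eq_vsmow = equilibrated_source_delta(d_water_liquid, cfg.Tleaf, consts)
    d_eq = vsmow_to_co2_scale(d_eq_vsmow, consts) / 1000.0  # fraction
    de = delta_e_co2 / 1000.0
    a_bar = consts.a_bar / 1000.0
    cm_term = cm_iso / (ca_leaf - cm_iso)
    do = de
    for _ in range(100):
        dea = (1.0 + d_eq) / (1.0 + do) - 1.0
        d_obs = a_bar + cm_term * dea
        do_new = (d_obs + xi * (1.0 + d_obs) * de) / (xi * (1.0 + d_obs) - d_obs)
        if abs(do_new - do) < 1e-16:
            do = do_new
            break
        do = do_new

    rng = cfg.rng("isotope")
    records = []
    for _ in range(n_readings):
        records.append(
            IsotopeExchangeRecord(
                Ce=ce,
                Co=co_wet,
                # the inlet is a calibrated reference gas characterised over the
                # whole campaign; per-reading measurement noise applies to the
                # chamber (outlet) delta only
                delta_e=delta_e_co2,
                delta_o=do * 1000.0 + rng.normal(0.0, cfg.sigma_delta),
                delta_vapor_in=water_delta + rng.normal(0.0, cfg.sigma_delta_vapor),
                delta_vapor_out=water_delta + rng.normal(0.0, cfg.sigma_delta_vapor),
                flow=u,
                leaf_area=s,
                Tleaf=cfg.Tleaf,
                Patm=cfg.Patm,
                A=a_op + rng.normal(0.0, cfg.sigma_A),
                Ci=ci_op / cfg.Patm,  # back to umol mol-1
                gsw=cfg.gsw,
                E=e_leaf,
            )
        )
    return records


def gen_stopped_flow(
    P: float,
    geom: CellGeometry,
    duration: float = 0.2,
    n_samples: int = 400,
    cfg: SimulationConfig = SimulationConfig(),
    amplitude: float = 1.0,
    baseline: float = 0.2,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> StoppedFlowTrace:
    """Simulate a stopped-flow acidification trace for permeability ``P`` (m s-1).

    Exponential quench with k = P * (S/V) / scale and multiplicative Gaussian
    noise sigma_F.  Pass an explicit ``rng`` to draw several traces from one
    stream.
    """
    if not P > 0:
        raise DomainError("P must be strictly positive")
    if rng is None:
        rng = cfg.rng("stopped_flow")
    k = P * surface_to_volume(geom) / scale
    t = np.linspace(0.0, duration, n_samples)
    f = baseline + amplitude * np.exp(-k * t)
    if cfg.sigma_F > 0:
        f = f * (1.0 + rng.normal(0.0, cfg.sigma_F, size=f.shape))
    return StoppedFlowTrace(t=t, F=f)


def _logistic(t: np.ndarray, od0: float, r: float, K: float) -> np.ndarray:
    if od0 <= 0:
        return np.zeros_like(t)
    return K / (1.0 + (K / od0 - 1.0) * np.exp(-r * t))


def gen_growth_curves(
    survival_frac: float,
    r: float = 0.45,
    K: float = 1.2,
    od0: float = 0.02,
    duration_h: float = 30.0,
    dt_h: float = 1.0 / 6.0,
    cfg: SimulationConfig = SimulationConfig(),
    strain: str = "synthetic",
) -> tuple[GrowthCurve, GrowthCurve]:
    """Simulate a (treated, untreated) growth-curve pair.

    The untreated culture grows logistically from ``od0``.  Freeze-thaw
    treatment kills all but ``survival_frac`` of the inoculum; dead cells
    still scatter light, so the treated culture starts at the same OD but
    only its viable fraction grows, which shows up as a longer effective
    lag.  10-min sampling by default, additive OD noise, readings clipped
    at zero.
    """
    if not 0.0 <= survival_frac <= 1.0:
        raise DomainError("survival_frac must lie in [0, 1]")
    if not (r > 0 and K > 0 and od0 > 0):
        raise DomainError("r, K and od0 must be positive")
    rng = cfg.rng("growth")
    t = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    od_u = _logistic(t, od0, r, K)
    dead = od0 * (1.0 - survival_frac)
    od_t = dead + _logistic(t, od0 * survival_frac, r, K - dead)
    if cfg.sigma_od > 0:
        od_u = np.maximum(od_u + rng.normal(0.0, cfg.sigma_od, size=t.shape), 0.0)
        od_t = np.maximum(od_t + rng.normal(0.0, cfg.sigma_od, size=t.shape), 0.0)
    treated = GrowthCurve(t=t, od=od_t, well_id="T1", strain=strain, condition="treated")
    untreated = GrowthCurve(t=t, od=od_u, well_id="U1", strain=strain, condition="untreated")
    return treated, untreated
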