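"""Mesophyll conductance from C18O16O discrimination.

Inside a C4 mesophyll cell, carbonic anhydrase (CA) exchanges oxygen atoms
between CO2 and cytosolic water, so CO2 diffusing back out of the leaf carries
the 18O signature of leaf water.  The stronger the retro-diffusion (the higher
the CO2 partial pressure Cm at the exchange site), the larger the apparent
discrimination against C18O16O.  Measured open-chamber discrimination
therefore locates Cm between the diffusional floor (a_bar) and the isotopic
source enrichment, and the mesophyll conductance follows from
g_m = A / (Ci - Cm).

Two estimation modes are provided:

* ``equilibrium`` — CO2 assumed fully equilibrated with cytosolic water
  (CA fast; the study's primary calculation);
* ``ca_limited`` — a finite CA hydration constant k_CA partially equilibrates
  CO2; incomplete equilibration is treated as a series resistance,
  1/g_m = 1/g_m,eq - 3/k_CA (factor 3 from the three oxygen positions
  exchanged per hydration cycle).  This is a documented approximation and the
  results carry metadata saying which variant produced them.

All delta arithmetic uses exact isotope-ratio products, never additive
approximations.  Deltas are per mil at the API surface, fractions internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FitError

__all__ = [
    "IsotopeExchangeRecord",
    "FractionationConstants",
    "CAKinetics",
    "DEFAULT_CONSTANTS",
    "observed_discrimination",
    "epsilon_w",
    "epsilon_liquid_vapor",
    "equilibrated_source_delta",
    "vsmow_to_co2_scale",
    "co2_to_vsmow_scale",
    "delta_ea",
    "cm_from_discrimination",
    "gm_equilibrium",
    "gm_ca_corrected",
    "IsotopeGmModel",
    "IsotopeGmResults",
    "estimate_gm",
]


@dataclass(frozen=True)
class IsotopeExchangeRecord:
    """One paired gas-exchange / isotope reading from an open chamber.

    CO2 mole fractions in umol mol-1; CO2 deltas on the instrument (VPDB-CO2)
    scale, water-vapor deltas on VSMOW, all in per mil.  ``Co`` and
    ``delta_o`` are outlet (chamber) air, ``Ce``/``delta_e`` inlet air.
    Gas-exchange context: A (umol m-2 s-1), Ci (umol mol-1), gsw and E
    (mol m-2 s-1), flow (umol s-1), leaf_area (m2).
    """

    Ce: float
    Co: float
    delta_e: float
    delta_o: float
    delta_vapor_in: float
    delta_vapor_out: float
    flow: float
    leaf_area: float
    Tleaf: float
    Patm: float
    A: float
    Ci: float
    gsw: float
    E: float

    def __post_init__(self) -> None:
        if not self.leaf_area > 0:
            raise DomainError("leaf_area must be positive")
        if not self.flow > 0:
            raise DomainError("flow must be positive")
        if not self.Patm > 0:
            raise DomainError("Patm must be positive")


@dataclass(frozen=True)
class FractionationConstants:
    """Fractionation factors and scale conversions for the 18O pipeline.

    a_bar : per mil
        Weighted diffusional fractionation of C18O16O through boundary layer
        and stomata (default 8.8, the in-air diffusional value; boundary-layer
        weighting neglected at typical chamber flow rates).
    eps_w_a, eps_w_b : per mil coefficients
        CO2-water 18O equilibrium fractionation eps_w(T) = a/T - b with T in
        kelvin (default 17604/T - 17.93, i.e. 41.1 per mil at 25 C).
    scale_ratio : dimensionless
        Ratio factor converting VPDB-CO2-scale deltas to VSMOW:
        (1 + d_VSMOW) = scale_ratio * (1 + d_VPDB-CO2).
    """

    a_bar: float = 8.8
    eps_w_a: float = 17604.0
    eps_w_b: float = 17.93
    scale_ratio: float = 1.04143

    def __post_init__(self) -> None:
        if not 0.0 < self.a_bar < 20.0:
            raise DomainError("a_bar must lie in (0, 20) per mil")
        ew25 = self.eps_w_a / 298.15 - self.eps_w_b
        if not 35.0 < ew25 < 50.0:
            raise DomainError(
                f"eps_w(25 C) = {ew25:.2f} per mil outside plausible (35, 50)"
            )


DEFAULT_CONSTANTS = FractionationConstants()


@dataclass(frozen=True)
class CAKinetics:
    """Carbonic-anhydrase CO2 hydration rate constant, mol m-2 s-1 bar-1."""

    kCA: float = 6.5

    def __post_init__(self) -> None:
        if not self.kCA > 0:
            raise DomainError("kCA must be strictly positive")


# --- delta/ratio algebra helpers (fractions, not per mil) -------------------


def _permil_to_frac(x: float) -> float:
    return x / 1000.0


def _frac_to_permil(x: float) -> float:
    return x * 1000.0


def dry_outlet_co2(rec: IsotopeExchangeRecord, ternary: bool = True) -> float:
    """Outlet CO2 mole fraction corrected for transpiration dilution.

    The leaf adds water vapor to the chamber air stream, diluting the outlet
    CO2 mole fraction; the ternary toggle converts the wet-basis reading back
    to the dry-air basis of the inlet: Co_dry = Co * (1 + E*s/u).
    """
    if not ternary:
        return rec.Co
    return rec.Co * (1.0 + rec.E * rec.leaf_area * 1e6 / rec.flow)


def observed_discrimination(rec: IsotopeExchangeRecord, ternary: bool = True) -> float:
    """Open-chamber C18O16O discrimination Delta_obs in per mil.

    Mass-balance form with xi = Ce/(Ce - Co):

        Delta_obs = xi*(d_o - d_e) / (1 + d_o - xi*(d_o - d_e))

    where the deltas are fractions internally.  Requires net CO2 drawdown
    (Ce != Co after the ternary dry-air correction).
    """
    co = dry_outlet_co2(rec, ternary)
    if rec.Ce == co:
        raise DomainError("no net CO2 drawdown (Ce equals Co); xi undefined")
    xi = rec.Ce / (rec.Ce - co)
    do = _permil_to_frac(rec.delta_o)
    de = _permil_to_frac(rec.delta_e)
    num = xi * (do - de)
    return _frac_to_permil(num / (1.0 + do - num))


def epsilon_w(Tleaf: float, consts: FractionationConstants = DEFAULT_CONSTANTS) -> float:
    """CO2-water 18O equilibrium fractionation (per mil) at leaf temperature (C).

    Rational form a/T - b in absolute temperature; decreasing in temperature,
    41.1 per mil at 25 C with the default coefficients.
    """
    if not 0.0 < Tleaf < 50.0:
        raise DomainError("Tleaf must lie in (0, 50) C")
    t_k = Tleaf + 273.15
    return consts.eps_w_a / t_k - consts.eps_w_b


def epsilon_liquid_vapor(Tleaf: float) -> float:
    """Equilibrium liquid-vapor 18O fractionation of water (per mil), Majoube form.

    10^3 ln(alpha) = 1.137e6/T^2 - 0.4156e3/T - 2.0667; ~9.3 per mil at 25 C.
    """
    if not 0.0 < Tleaf < 50.0:
        raise DomainError("Tleaf must lie in (0, 50) C")
    t_k = Tleaf + 273.15
    ln_alpha = 1.137e6 / t_k**2 - 415.6 / t_k - 2.0667
    return _frac_to_permil(math.exp(ln_alpha / 1000.0) - 1.0)


def liquid_water_from_vapor(delta_vapor: float, Tleaf: float) -> float:
    """delta-18O of liquid water in equilibrium with measured vapor (per mil VSMOW)."""
    dv = _permil_to_frac(delta_vapor)
    eps = _permil_to_frac(epsilon_liquid_vapor(Tleaf))
    return _frac_to_permil((1.0 + dv) * (1.0 + eps) - 1.0)


def equilibrated_source_delta(
    delta_water: float,
    Tleaf: float,
    consts: FractionationConstants = DEFAULT_CONSTANTS,
) -> float:
    """delta-18O of CO2 in isotopic equilibrium with water of given delta (per mil).

    Exact ratio algebra on the water's own scale:
    (1 + d_eq) = (1 + d_water) * (1 + eps_w(Tleaf)).
    """
    dw = _permil_to_frac(delta_water)
    ew = _permil_to_frac(epsilon_w(Tleaf, consts))
    return _frac_to_permil((1.0 + dw) * (1.0 + ew) - 1.0)


def vsmow_to_co2_scale(
    delta_vsmow: float, consts: FractionationConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert a VSMOW-scale delta (per mil) to the VPDB-CO2 instrument scale."""
    return _frac_to_permil(
        (1.0 + _permil_to_frac(delta_vsmow)) / consts.scale_ratio - 1.0
    )


def co2_to_vsmow_scale(
    delta_co2: float, consts: FractionationConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert a VPDB-CO2-scale delta (per mil) to VSMOW."""
    return _frac_to_permil(
        (1.0 + _permil_to_frac(delta_co2)) * consts.scale_ratio - 1.0
    )


def delta_ea(delta_eq_co2: float, delta_chamber_co2: float) -> float:
    """18O enrichment (per mil) of equilibrated CO2 relative to chamber CO2.

    Exact ratio difference: Delta_ea = (1 + d_eq)/(1 + d_a) - 1, both deltas
    on the same (VPDB-CO2) scale.
    """
    deq = _permil_to_frac(delta_eq_co2)
    da = _permil_to_frac(delta_chamber_co2)
    return _frac_to_permil((1.0 + deq) / (1.0 + da) - 1.0)


def cm_from_discrimination(
    delta_obs: float, d_ea: float, a_bar: float, Ca: float
) -> float:
    """Invert the discrimination model for the exchange-site CO2 pressure Cm.

    Model: Delta_obs = a_bar + (Cm / (Ca - Cm)) * Delta_ea, hence

        Cm = Ca * (Delta_obs - a_bar) / (Delta_obs - a_bar + Delta_ea)

    All discrimination arguments in per mil, Ca and Cm in ubar.
    """
    if not Ca > 0:
        raise DomainError("Ca must be positive")
    x = _permil_to_frac(delta_obs) - _permil_to_frac(a_bar)
    dea = _permil_to_frac(d_ea)
    if x <= 0.0:
        raise DomainError(
            f"discrimination {delta_obs:.3f} per mil below diffusional floor "
            f"a_bar = {a_bar:.3f} per mil; no retro-diffusion signal"
        )
    if x + dea == 0.0:
        raise DomainError("Delta_ea equals a_bar - Delta_obs; inversion singular")
    return Ca * x / (x + dea)


def gm_equilibrium(A: float, Ci: float, Cm: float) -> float:
    """Mesophyll conductance g_m = A / (Ci - Cm), mol m-2 s-1 bar-1."""
    if Ci <= Cm:
        raise DomainError(f"Ci ({Ci:.2f} ubar) must exceed Cm ({Cm:.2f} ubar)")
    return A / (Ci - Cm)


def gm_ca_corrected(gm_eq: float, ca_kin: CAKinetics) -> float:
    """CA-limited g_m from the full-equilibrium estimate (series-resistance form).

    1/g_m = 1/g_m,eq - 3/k_CA.  Always >= g_m,eq; reduces to g_m,eq as
    k_CA -> infinity.  Diverges as g_m,eq -> k_CA/3, where the equilibrium
    assumption has absorbed the whole CA resistance.
    """
    if not gm_eq > 0:
        raise DomainError("gm_eq must be strictly positive")
    if gm_eq >= ca_kin.kCA / 3.0:
        raise DomainError(
            f"gm_eq = {gm_eq:.3f} >= kCA/3 = {ca_kin.kCA / 3.0:.3f}: "
            "CA too slow for the series correction - full model required"
        )
    return 1.0 / (1.0 / gm_eq - 3.0 / ca_kin.kCA)


# --- batch estimator --------------------------------------------------------


class IsotopeGmModel:
    """Estimator of mesophyll conductance from isotope-exchange records.

    Per-record pipeline: observed_discrimination -> leaf-water delta from
    chamber vapor (liquid-vapor equilibrium at Tleaf) -> equilibrated CO2
    delta (CO2-water equilibrium, scale-converted) -> Delta_ea ->
    cm_from_discrimination -> gm_equilibrium (-> gm_ca_corrected).
    Invalid records are excluded with per-record reasons, never silently.

    Parameters
    ----------
    records : list of IsotopeExchangeRecord
    constants : FractionationConstants
    ternary : bool
        Apply the transpiration dry-air correction to the outlet CO2
        (default True).
    """

    def __init__(
        self,
        records: list[IsotopeExchangeRecord],
        constants: FractionationConstants = DEFAULT_CONSTANTS,
        ternary: bool = True,
    ):
        if not records:
            raise DomainError("at least one isotope-exchange record required")
        self.records = list(records)
        self.constants = constants
        self.ternary = ternary

    def _invert_record(
        self, rec: IsotopeExchangeRecord, mode: str, ca_kin: CAKinetics | None
    ) -> dict:
        out: dict = {"valid": False, "reason": ""}
        try:
            d_obs = observed_discrimination(rec, self.ternary)
            out["delta_obs"] = d_obs
            ca = dry_outlet_co2(rec, self.ternary) * rec.Patm  # ubar, chamber air
            ci = rec.Ci * rec.Patm
            d_water = liquid_water_from_vapor(rec.delta_vapor_out, rec.Tleaf)
            d_eq_vsmow = equilibrated_source_delta(d_water, rec.Tleaf, self.constants)
            d_eq_co2 = vsmow_to_co2_scale(d_eq_vsmow, self.constants)
            d_ea = delta_ea(d_eq_co2, rec.delta_o)
            cm = cm_from_discrimination(d_obs, d_ea, self.constants.a_bar, ca)
            out.update(Ca_ubar=ca, Ci_ubar=ci, delta_ea=d_ea, Cm_ubar=cm)
            if not 0.0 < cm < ca:
                raise DomainError(f"Cm = {cm:.2f} ubar outside (0, Ca = {ca:.2f})")
            gm = gm_equilibrium(rec.A, ci, cm)
            out["gm_equilibrium"] = gm
            if mode == "ca_limited":
                gm = gm_ca_corrected(gm, ca_kin)
            out["gm"] = gm
            out["valid"] = True
        except DomainError as exc:
            out["reason"] = str(exc)
        return out

    def fit(
        self,
        mode: str = "equilibrium",
        ca_kin: CAKinetics | None = None,
        average: str = "per_record",
    ) -> "IsotopeGmResults":
        """Estimate g_m.

        mode : {"equilibrium", "ca_limited"}
        ca_kin : CAKinetics, required for ca_limited mode.
        average : {"per_record", "invert_mean"}
            Average the per-reading inversions (default, matching per-reading
            measurement protocols) or invert the mean record.
        """
        if mode not in ("equilibrium", "ca_limited"):
            raise DomainError(f"unknown mode {mode!r}")
        if mode == "ca_limited" and ca_kin is None:
            raise DomainError("ca_kin (CAKinetics) required for ca_limited mode")
        if average not in ("per_record", "invert_mean"):
            raise DomainError(f"unknown averaging policy {average!r}")

        records = self.records
        if average == "invert_mean":
            fields = IsotopeExchangeRecord.__dataclass_fields__
            mean_rec = IsotopeExchangeRecord(
                **{
                    name: float(np.mean([getattr(r, name) for r in records]))
                    for name in fields
                }
            )
            records = [mean_rec]

        rows = [self._invert_record(r, mode, ca_kin) for r in records]
        table = pd.DataFrame(rows)
        valid = table[table["valid"]]
        if valid.empty:
            reasons = "; ".join(
                f"record {i}: {r}" for i, r in zip(table.index, table["reason"])
            )
            raise FitError(f"all records invalid: {reasons}")
        gms = valid["gm"].to_numpy()
        n = len(gms)
        se = float(np.std(gms, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        metadata = {
            "mode": mode,
            "ca_correction": "series-resistance approximation (1/gm = 1/gm_eq - 3/kCA)"
            if mode == "ca_limited"
            else None,
            "kCA": ca_kin.kCA if ca_kin is not None else None,
            "ternary": self.ternary,
            "a_bar_permil": self.constants.a_bar,
            "eps_w_25C_permil": epsilon_w(25.0, self.constants),
            "scale_ratio": self.constants.scale_ratio,
            "averaging": average,
        }
        return IsotopeGmResults(
            model=self,
            per_record=table,
            gm_mean=float(np.mean(gms)),
            gm_se=se,
            n_used=n,
            n_excluded=int(len(table) - n),
            metadata=metadata,
        )


@dataclass
class IsotopeGmResults:
    """Per-record and aggregated mesophyll-conductance estimates."""

    model: IsotopeGmModel
    per_record: pd.DataFrame
    gm_mean: float
    gm_se: float
    n_used: int
    n_excluded: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        md = self.metadata
        lines = [
            "Mesophyll conductance from C18O16O discrimination",
            "=" * 50,
            f"mode            : {md['mode']}"
            + (f" (kCA = {md['kCA']} mol m-2 s-1 bar-1)" if md["kCA"] else ""),
            f"records used    : {self.n_used} (excluded: {self.n_excluded})",
            f"g_m             : {self.gm_mean:.4f} +/- {self.gm_se:.4f} mol m-2 s-1 bar-1",
            f"a_bar           : {md['a_bar_permil']:g} per mil",
            f"eps_w(25 C)     : {md['eps_w_25C_permil']:.2f} per mil",
            f"ternary corr.   : {md['ternary']}",
        ]
        if md.get("ca_correction"):
            lines.append(f"CA correction   : {md['ca_correction']}")
        return "\n".join(lines)


def estimate_gm(
    records: list[IsotopeExchangeRecord],
    consts: FractionationConstants = DEFAULT_CONSTANTS,
    mode: str = "equilibrium",
    ca_kin: CAKinetics | None = None,
    ternary: bool = True,
    average: str = "per_record",
) -> IsotopeGmResults:
    """Functional wrapper over :class:`IsotopeGmModel`."""
    return IsotopeGmModel(records, constants=consts, ternary=ternary).fit(
        mode=mode, ca_kin=ca_kin, average=average
    )
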