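"""A-Ci curve containers and initial-slope / A_max analysis.

An A-Ci curve is a series of steady-state gas-exchange readings taken while
stepping the ambient CO2 mole fraction (here 0-1600 ppm); the net assimilation
rate A is regressed on the intercellular CO2 partial pressure Ci over the
low-Ci window to obtain the initial slope, the quantity the slope-conductance
relation in :mod:`mesokit.c4model` interprets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, FitError

__all__ = [
    "GasExchangeRecord",
    "ACiCurve",
    "InitialSlopeModel",
    "InitialSlopeResults",
    "fit_initial_slope",
    "amax",
]

#: relative and absolute slack on the Ci <= Ca check; at very low Ca,
#: respiration makes Ci legitimately exceed Ca by a few ubar.
_CI_REL_EPS = 0.05
_CI_ABS_SLACK = 15.0  # ubar


@dataclass(frozen=True)
class GasExchangeRecord:
    """One steady-state gas-exchange reading (partial pressures in ubar)."""

    Ca: float
    Ci: float
    A: float
    gsw: float = float("nan")
    Tleaf: float = 25.0
    Patm: float = 1.0

    def __post_init__(self) -> None:
        if not self.Patm > 0:
            raise DomainError("Patm must be positive")
        if self.Ci > self.Ca * (1.0 + _CI_REL_EPS) + _CI_ABS_SLACK:
            raise DomainError(
                f"Ci={self.Ci:.2f} implausibly exceeds Ca={self.Ca:.2f}"
            )


@dataclass
class ACiCurve:
    """Ordered A-Ci series (ascending Ca setpoint) with genotype metadata."""

    records: list[GasExchangeRecord]
    genotype: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if len(self.records) < 4:
            raise DomainError("ACiCurve needs at least 4 records")
        ca = self.ca
        if np.any(np.diff(ca) <= 0):
            raise DomainError("Ca setpoints must be strictly increasing")

    @property
    def ca(self) -> np.ndarray:
        return np.array([r.Ca for r in self.records])

    @property
    def ci(self) -> np.ndarray:
        return np.array([r.Ci for r in self.records])

    @property
    def a(self) -> np.ndarray:
        return np.array([r.A for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Ca_ubar": self.ca,
                "Ci_ubar": self.ci,
                "A": self.a,
                "gsw": [r.gsw for r in self.records],
                "Tleaf": [r.Tleaf for r in self.records],
                "Patm_bar": [r.Patm for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, genotype: str = "", replicate_id: str = ""
    ) -> "ACiCurve":
        records = [
            GasExchangeRecord(
                Ca=row.Ca_ubar,
                Ci=row.Ci_ubar,
                A=row.A,
                gsw=getattr(row, "gsw", float("nan")),
                Tleaf=getattr(row, "Tleaf", 25.0),
                Patm=getattr(row, "Patm_bar", 1.0),
            )
            for row in df.itertuples()
        ]
        return cls(records, genotype=genotype, replicate_id=replicate_id)


class InitialSlopeModel:
    """OLS model for the initial (low-Ci) slope of an A-Ci curve.

    Parameters
    ----------
    curve : ACiCurve
        The measured curve.
    ci_max : float
        Upper Ci bound (ubar) of the fitting window.  The default 60 ubar
        keeps PEPC in its quasi-linear regime (Kp = 82 ubar).
    """

    def __init__(self, curve: ACiCurve, ci_max: float = 60.0):
        self.curve = curve
        self.ci_max = float(ci_max)

    def fit(self) -> "InitialSlopeResults":
        mask = self.curve.ci <= self.ci_max
        n = int(mask.sum())
        if n < 3:
            raise FitError(
                f"only {n} records with Ci <= ci_max={self.ci_max} ubar; need >= 3"
            )
        x = self.curve.ci[mask]
        y = self.curve.a[mask]
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return InitialSlopeResults(model=self, _sm_results=res, n_points=n)


@dataclass
class InitialSlopeResults:
    """Initial-slope regression results.

    ``slope`` is dA/dCi in mol m-2 s-1 bar-1 (numerically umol m-2 s-1
    ubar-1); ``gm()`` maps it to a mesophyll conductance through the
    slope-conductance relation.
    """

    model: InitialSlopeModel
    _sm_results: object
    n_points: int

    @property
    def slope(self) -> float:
        return float(self._sm_results.params[1])

    @property
    def intercept(self) -> float:
        return float(self._sm_results.params[0])

    @property
    def slope_stderr(self) -> float:
        se = float(self._sm_results.bse[1])
        return 0.0 if np.isnan(se) else se

    def gm(self, Vpmax: float = 250.0, Kp: float = 82.0) -> float:
        from .c4model import gm_from_initial_slope

        return gm_from_initial_slope(self.slope, Vpmax, Kp)

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "Initial slope of A-Ci curve (OLS)",
            "=" * 42,
            f"genotype       : {c.genotype or '-'}",
            f"replicate      : {c.replicate_id or '-'}",
            f"Ci window      : <= {self.model.ci_max:g} ubar ({self.n_points} points)",
            f"slope dA/dCi   : {self.slope:.4f} +/- {self.slope_stderr:.4f} mol m-2 s-1 bar-1",
            f"intercept      : {self.intercept:.4f} umol m-2 s-1",
            f"R-squared      : {float(self._sm_results.rsquared):.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: points in the window, the fitted line, full curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.ci, c.a, "o", color="0.6", label="all records")
        mask = c.ci <= self.model.ci_max
        ax.plot(c.ci[mask], c.a[mask], "o", color="C0", label="fit window")
        xx = np.linspace(0.0, self.model.ci_max, 50)
        ax.plot(xx, self.intercept + self.slope * xx, "-", color="C3", label="OLS fit")
        ax.set_xlabel("Ci (ubar)")
        ax.set_ylabel("A (umol m-2 s-1)")
        ax.legend()
        return ax


def fit_initial_slope(
    curve: ACiCurve, ci_max: float = 60.0
) -> tuple[float, float, float, int]:
    """Fit the initial slope; returns ``(slope, intercept, stderr, n_points)``."""
    res = InitialSlopeModel(curve, ci_max=ci_max).fit()
    return res.slope, res.intercept, res.slope_stderr, res.n_points


def amax(curve: ACiCurve, plateau_fraction: float = 0.9) -> float:
    """Saturating assimilation rate: mean A over the high-Ca plateau.

    Records whose Ca exceeds ``plateau_fraction`` of the maximum Ca setpoint
    are averaged; ``plateau_fraction=1.0`` degenerates to the single highest
    setpoint.
    """
    if not 0.0 < plateau_fraction <= 1.0:
        raise DomainError("plateau_fraction must be in (0, 1]")
    ca = curve.ca
    cutoff = plateau_fraction * ca.max() * (1.0 - 1e-12)
    mask = ca >= cutoff
    if not mask.any():
        raise FitError("no records qualify for the A_max plateau window")
    return float(curve.a[mask].mean())
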