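"""Membrane CO2 permeability from stopped-flow acidification kinetics.

Yeast cells loaded with a pH-sensitive fluorescein dye are rapidly mixed with
CO2-enriched buffer; CO2 entering the cell is hydrated (carbonic anhydrase is
co-expressed in excess) and the resulting acidification quenches the dye.
With entry limited by the membrane, the quench follows a single exponential
F(t) = baseline + amplitude * exp(-k t), and the rate constant maps to a
permeability through the cell's surface-to-volume ratio:

    P_CO2 = k * V/S = k * d / 6        (spherical-equivalent diameter d)

Absolute calibration (buffering capacity, CO2 gradient normalisation) enters
as a configurable scale factor; recovery of simulated permeabilities is
scale-consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConvergenceError, DomainError, FitError

__all__ = [
    "StoppedFlowTrace",
    "CellGeometry",
    "surface_to_volume",
    "AcidificationModel",
    "AcidificationResults",
    "fit_acidification_rate",
    "pco2_from_rate",
    "batch_permeability",
    "BatchPermeabilityResults",
]


@dataclass
class StoppedFlowTrace:
    """Time-resolved fluorescence trace: t in s (from 0, increasing), F in a.u."""

    t: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise DomainError("t and F must be 1-D arrays of equal length")
        if len(self.t) < 20:
            raise DomainError("trace needs at least 20 samples")
        if abs(self.t[0]) > 1e-12:
            raise DomainError("time axis must start at 0")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise DomainError("fluorescence values must be finite")


@dataclass(frozen=True)
class CellGeometry:
    """Mean spherical-equivalent cell diameter in metres."""

    diameter: float

    def __post_init__(self) -> None:
        if not 1e-7 < self.diameter < 1e-4:
            raise DomainError(
                f"diameter {self.diameter!r} m outside plausible cell range (1e-7, 1e-4)"
            )


def surface_to_volume(geom: CellGeometry) -> float:
    """Surface-to-volume ratio of a sphere, 6/d, in m-1."""
    return 6.0 / geom.diameter


class AcidificationModel:
    """Single-exponential fit of a stopped-flow quench trace.

    Parameters
    ----------
    trace : StoppedFlowTrace
    dead_time : float
        Mixing dead-time (s) excluded from the fit window; default 5 ms.
    """

    def __init__(self, trace: StoppedFlowTrace, dead_time: float = 5e-3):
        if dead_time < 0:
            raise DomainError("dead_time must be non-negative")
        self.trace = trace
        self.dead_time = float(dead_time)

    def fit(self) -> "AcidificationResults":
        t, F = self.trace.t, self.trace.F
        mask = t >= self.dead_time
        if mask.sum() < 10:
            raise FitError("fewer than 10 samples after the dead-time window")
        t, F = t[mask], F[mask]

        span = float(F.max() - F.min())
        if span <= 0.0 or span < 1e-9 * max(1.0, abs(float(F.mean()))):
            raise FitError("no acidification signal: trace is flat")

        # initial guesses: tail as baseline, log-linear slope for k
        ntail = max(3, len(F) // 20)
        base0 = float(F[-ntail:].mean())
        amp0 = float(F[0] - base0)
        if amp0 <= 0.0:
            raise FitError("no acidification signal: fluorescence does not decay")
        resid0 = F - base0
        pos = resid0 > 0.05 * amp0
        if pos.sum() >= 3:
            slope = np.polyfit(t[pos], np.log(resid0[pos]), 1)[0]
            k0 = max(-float(slope), 1e-3)
        else:
            k0 = 1.0 / max(t[-1], 1e-6)

        def model(tt, base, amp, k):
            return base + amp * np.exp(-k * tt)

        try:
            popt, pcov = curve_fit(
                model,
                t,
                F,
                p0=(base0, amp0, k0),
                bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as exc:
            raise ConvergenceError(f"exponential fit failed to converge: {exc}") from exc

        base, amp, k = (float(v) for v in popt)
        resid = F - model(t, *popt)
        rss = float(resid @ resid)
        tss = float(((F - F.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        resid_sd = float(np.sqrt(rss / max(len(F) - 3, 1)))
        if k <= 0 or amp <= 5.0 * resid_sd:
            raise FitError(
                f"no acidification signal: amplitude {amp:.3g} vs residual sd "
                f"{resid_sd:.3g}, k = {k:.3g} s-1"
            )
        if k * (t[-1] - t[0]) < 1.0:
            # less than one e-fold inside the window: k, amplitude and
            # baseline are mutually degenerate
            raise FitError(
                f"no resolvable acidification signal: k = {k:.3g} s-1 implies "
                f"<1 e-fold of decay within the {t[-1] - t[0]:.3g} s window"
            )
        k_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
        return AcidificationResults(
            model=self,
            k=k,
            k_stderr=k_se,
            amplitude=amp,
            baseline=base,
            r_squared=r2,
            resid_sd=resid_sd,
            n_points=len(F),
        )


@dataclass
class AcidificationResults:
    """Exponential quench fit: rate constant k (s-1) and fit diagnostics."""

    model: AcidificationModel
    k: float
    k_stderr: float
    amplitude: float
    baseline: float
    r_squared: float
    resid_sd: float
    n_points: int

    def pco2(self, geom: CellGeometry, scale: float = 1.0) -> float:
        """Membrane CO2 permeability (m s-1) for the given cell geometry."""
        return pco2_from_rate(self.k, geom, scale=scale)

    def summary(self) -> str:
        lines = [
            "Stopped-flow acidification fit",
            "=" * 40,
            f"rate constant k : {self.k:.2f} +/- {self.k_stderr:.2f} s-1",
            f"amplitude       : {self.amplitude:.4g} a.u.",
            f"baseline        : {self.baseline:.4g} a.u.",
            f"R-squared       : {self.r_squared:.5f}",
            f"points fitted   : {self.n_points} (dead-time {self.model.dead_time*1e3:g} ms)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.model.trace
        ax.plot(tr.t, tr.F, ".", color="0.6", ms=3, label="trace")
        tt = np.linspace(self.model.dead_time, tr.t[-1], 200)
        ax.plot(
            tt,
            self.baseline + self.amplitude * np.exp(-self.k * tt),
            "-",
            color="C3",
            label=f"fit, k={self.k:.1f} s$^{{-1}}$",
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fluorescence (a.u.)")
        ax.legend()
        return ax


def fit_acidification_rate(
    trace: StoppedFlowTrace, dead_time: float = 5e-3
) -> tuple[float, float, float, float]:
    """Fit the quench; returns ``(k, amplitude, baseline, r_squared)``."""
    res = AcidificationModel(trace, dead_time=dead_time).fit()
    return res.k, res.amplitude, res.baseline, res.r_squared


def pco2_from_rate(k: float, geom: CellGeometry, scale: float = 1.0) -> float:
    """Convert a quench rate constant to CO2 permeability: P = scale * k * d/6."""
    if not k > 0:
        raise DomainError("rate constant k must be strictly positive")
    if not scale > 0:
        raise DomainError("scale factor must be strictly positive")
    return scale * k / surface_to_volume(geom)


@dataclass
class BatchPermeabilityResults:
    """Aggregated permeability over a batch of traces; failures kept visible."""

    p_mean: float
    p_se: float
    n: int
    per_trace: list[float]
    failures: list[tuple[int, str]] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Batch CO2 permeability",
            "=" * 40,
            f"P_CO2 : {self.p_mean:.4g} +/- {self.p_se:.2g} m s-1 (n = {self.n})",
        ]
        for idx, reason in self.failures:
            lines.append(f"  trace {idx} failed: {reason}")
        return "\n".join(lines)


def batch_permeability(
    traces: list[StoppedFlowTrace],
    geom: CellGeometry,
    n_min: int = 3,
    dead_time: float = 5e-3,
    scale: float = 1.0,
) -> BatchPermeabilityResults:
    """Fit every trace and average the permeabilities.

    Traces whose fit fails are recorded as (index, reason) pairs, not silently
    dropped; fewer than ``n_min`` successes is an error.
    """
    ps: list[float] = []
    failures: list[tuple[int, str]] = []
    for i, tr in enumerate(traces):
        try:
            res = AcidificationModel(tr, dead_time=dead_time).fit()
            ps.append(res.pco2(geom, scale=scale))
        except (FitError, ConvergenceError, DomainError) as exc:
            failures.append((i, str(exc)))
    if len(ps) < n_min:
        raise FitError(
            f"only {len(ps)} successful fits (< n_min = {n_min}); "
            + "; ".join(f"trace {i}: {r}" for i, r in failures)
        )
    arr = np.array(ps)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return BatchPermeabilityResults(
        p_mean=float(arr.mean()),
        p_se=se,
        n=len(arr),
        per_trace=ps,
        failures=failures,
    )
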