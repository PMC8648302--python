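"""Freeze-thaw survival from plate-reader growth curves.

Water-permeable aquaporins protect yeast against freeze-thaw damage, so
survival after a single freeze-thaw cycle reads out functional water
permeability.  Survival is quantified as the percent area under the
log-transformed, baseline-anchored growth curve (%AUC) of the treated culture
relative to its untreated control, integrated from time zero until the
untreated control reaches stationary phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DomainError, FitError

__all__ = [
    "GrowthCurve",
    "log_transform",
    "stationary_onset",
    "percent_auc",
    "plate_summary",
    "FreezeThawAssay",
    "FreezeThawResults",
]


@dataclass
class GrowthCurve:
    """OD-vs-time series for one well.

    t in hours (strictly increasing), od dimensionless (OD650).  When
    ``log_transformed`` is True the od values are natural-log OD and may be
    negative.
    """

    t: np.ndarray
    od: np.ndarray
    well_id: str = ""
    strain: str = ""
    condition: str = ""
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.t.shape != self.od.shape or self.t.ndim != 1:
            raise DomainError("t and od must be 1-D arrays of equal length")
        if len(self.t) < 4:
            raise DomainError("growth curve needs at least 4 samples")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise DomainError("OD values must be finite")
        if not self.log_transformed and np.any(self.od < 0):
            raise DomainError("raw OD values must be non-negative")


def log_transform(curve: GrowthCurve, floor: float = 1e-3) -> GrowthCurve:
    """Natural-log transform with a positive floor guarding blank/zero wells."""
    if not floor > 0:
        raise DomainError("floor must be strictly positive")
    if curve.log_transformed:
        return curve
    return replace(
        curve, od=np.log(np.maximum(curve.od, floor)), log_transformed=True
    )


def _rolling_slopes(curve: GrowthCurve, window: float) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of od over the trailing ``window`` hours at each time.

    Returns (times, slopes) for indices whose trailing window is fully inside
    the record.
    """
    t, y = curve.t, curve.od
    times, slopes = [], []
    for i in range(len(t)):
        if t[i] - t[0] < window:
            continue
        sel = (t > t[i] - window) & (t <= t[i])
        if sel.sum() < 2:
            continue
        slopes.append(np.polyfit(t[sel], y[sel], 1)[0])
        times.append(t[i])
    return np.array(times), np.array(slopes)


def stationary_onset(
    curve: GrowthCurve,
    slope_eps: float = 0.01,
    window: float = 2.0,
    floor: float = 1e-3,
) -> float:
    """Earliest time (h) after the growth phase where growth has plateaued.

    The log-transformed curve's rolling-window slope is computed at each
    sample; the onset is the first time at or after the slope maximum where
    the slope drops below ``slope_eps`` (per hour).
    """
    if not slope_eps > 0 or not window > 0:
        raise DomainError("slope_eps and window must be positive")
    logged = log_transform(curve, floor)
    times, slopes = _rolling_slopes(logged, window)
    if len(times) == 0:
        raise FitError("curve shorter than the rolling window")
    if slopes.max() < slope_eps:
        # never grew: degenerate plateau from the start
        return float(times[0])
    imax = int(np.argmax(slopes))
    for i in range(imax, len(times)):
        if slopes[i] < slope_eps:
            return float(times[i])
    raise FitError(
        "no plateau detected: rolling slope never fell below "
        f"slope_eps = {slope_eps} h-1; run longer or raise slope_eps"
    )


def _anchored_log(curve: GrowthCurve, floor: float) -> tuple[np.ndarray, np.ndarray]:
    logged = log_transform(curve, floor)
    return logged.t, logged.od - logged.od[0]


def _auc_to(t: np.ndarray, y: np.ndarray, t_end: float) -> float:
    """Trapezoid integral of y(t) over [t[0], t_end], interpolating the endpoint."""
    if t_end <= t[0]:
        return 0.0
    t_end = min(t_end, t[-1])
    mask = t <= t_end
    tt = t[mask]
    yy = y[mask]
    if tt[-1] < t_end:
        tt = np.append(tt, t_end)
        yy = np.append(yy, np.interp(t_end, t, y))
    return float(np.trapezoid(yy, tt))


def percent_auc(
    treated: GrowthCurve,
    untreated: GrowthCurve,
    floor: float = 1e-3,
    slope_eps: float = 0.01,
    window: float = 2.0,
    use_log: bool = True,
) -> float:
    """Percent area under the growth curve of treated relative to untreated.

    Both curves are log-transformed (unless ``use_log=False``), anchored to
    their t=0 value so the integral measures cumulative growth, and
    trapezoid-integrated from time zero to the untreated culture's stationary
    onset.  Curves on different time bases are linearly resampled onto the
    untreated grid.  Values above 100% (treated outgrowing the control) are
    preserved.
    """
    t_stat = stationary_onset(untreated, slope_eps=slope_eps, window=window, floor=floor)
    if use_log:
        tu, yu = _anchored_log(untreated, floor)
        tt_, yt = _anchored_log(treated, floor)
    else:
        tu, yu = untreated.t, untreated.od - untreated.od[0]
        tt_, yt = treated.t, treated.od - treated.od[0]
    if len(tt_) != len(tu) or not np.allclose(tt_, tu):
        yt = np.interp(tu, tt_, yt)
    auc_u = _auc_to(tu, yu, t_stat)
    if auc_u <= 0:
        raise FitError("control failed to grow: untreated AUC is non-positive")
    auc_t = _auc_to(tu, yt, t_stat)
    return 100.0 * auc_t / auc_u


def plate_summary(
    curves: list[GrowthCurve],
    pairing: list[tuple[str, str]],
    floor: float = 1e-3,
    slope_eps: float = 0.01,
    window: float = 2.0,
    use_log: bool = True,
) -> pd.DataFrame:
    """Per-strain mean +/- SE %AUC from explicitly paired wells.

    ``pairing`` lists (treated_well_id, untreated_well_id) tuples; pairing is
    never inferred from well order.  Returns a table with columns
    strain, mean_pct_auc, se_pct_auc, n_pairs.
    """
    by_well = {c.well_id: c for c in curves}
    rows = []
    for treated_id, untreated_id in pairing:
        try:
            treated = by_well[treated_id]
            untreated = by_well[untreated_id]
        except KeyError as exc:
            raise DomainError(f"pairing references unknown well {exc}") from exc
        pct = percent_auc(
            treated,
            untreated,
            floor=floor,
            slope_eps=slope_eps,
            window=window,
            use_log=use_log,
        )
        rows.append({"strain": treated.strain, "pct_auc": pct})
    if not rows:
        raise DomainError("pairing is empty")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("strain")["pct_auc"]
        .agg(
            mean_pct_auc="mean",
            se_pct_auc=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            n_pairs="count",
        )
        .reset_index()
    )
    return out


class FreezeThawAssay:
    """Plate-level freeze-thaw survival model (%AUC per strain)."""

    def __init__(
        self,
        curves: list[GrowthCurve],
        pairing: list[tuple[str, str]],
        floor: float = 1e-3,
        slope_eps: float = 0.01,
        window: float = 2.0,
        use_log: bool = True,
    ):
        self.curves = curves
        self.pairing = pairing
        self.floor = floor
        self.slope_eps = slope_eps
        self.window = window
        self.use_log = use_log

    def fit(self) -> "FreezeThawResults":
        table = plate_summary(
            self.curves,
            self.pairing,
            floor=self.floor,
            slope_eps=self.slope_eps,
            window=self.window,
            use_log=self.use_log,
        )
        return FreezeThawResults(model=self, table=table)


@dataclass
class FreezeThawResults:
    model: FreezeThawAssay
    table: pd.DataFrame

    def summary(self) -> str:
        lines = ["Freeze-thaw survival (%AUC)", "=" * 40]
        for row in self.table.itertuples():
            lines.append(
                f"{row.strain or '-':<12s}: {row.mean_pct_auc:7.2f} % "
                f"+/- {row.se_pct_auc:.2f} (n = {row.n_pairs})"
            )
        return "\n".join(lines)
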