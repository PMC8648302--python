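"""CSV dialects and run manifests.

Four plain-text record types are read and written:

* gas exchange:   ``Ca_ppm,Ci_ppm,A,gsw,Tleaf,Patm_bar``
* isotope flux:   ``Ce_ppm,Co_ppm,delta_e,delta_o,delta_vap_in,delta_vap_out,
  flow_umol_s,leaf_area_m2,Tleaf,Patm_bar,A,Ci_ppm,gsw,E``
* stopped flow:   ``t_s,F``
* plate reader:   ``well_id,strain,condition,t_h,od650[,pair_id]``

Mole fractions (ppm) are converted to partial pressures (ubar) via Patm; a
missing Patm column means exactly 1 bar and is logged as a warning.  Every
analysis run can be accompanied by a JSON manifest (command, config snapshot,
input hashes, version, seed, timestamp) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .aci import ACiCurve, GasExchangeRecord
from .errors import DomainError, ParseError
from .growth import GrowthCurve
from .isoflux import IsotopeExchangeRecord
from .permeability import StoppedFlowTrace

__all__ = [
    "read_gas_exchange_csv",
    "write_gas_exchange_csv",
    "read_isotope_csv",
    "write_isotope_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_plate_csv",
    "write_plate_csv",
    "RunManifest",
]

log = logging.getLogger("mesokit")

_FLOAT_FMT = "%.10g"


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _patm_column(df: pd.DataFrame, path) -> pd.Series:
    if "Patm_bar" in df.columns:
        return df["Patm_bar"]
    log.warning("%s: no Patm_bar column; assuming 1.0 bar exactly", path)
    return pd.Series(np.ones(len(df)))


def read_gas_exchange_csv(path, genotype: str = "", replicate_id: str = "") -> ACiCurve:
    """Read an A-Ci gas-exchange table; ppm converted to ubar via Patm."""
    df = _read_csv(path, ["Ca_ppm", "Ci_ppm", "A"])
    patm = _patm_column(df, path)
    try:
        records = [
            GasExchangeRecord(
                Ca=float(df["Ca_ppm"].iloc[i]) * float(patm.iloc[i]),
                Ci=float(df["Ci_ppm"].iloc[i]) * float(patm.iloc[i]),
                A=float(df["A"].iloc[i]),
                gsw=float(df["gsw"].iloc[i]) if "gsw" in df.columns else float("nan"),
                Tleaf=float(df["Tleaf"].iloc[i]) if "Tleaf" in df.columns else 25.0,
                Patm=float(patm.iloc[i]),
            )
            for i in range(len(df))
        ]
        return ACiCurve(records, genotype=genotype, replicate_id=replicate_id)
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_gas_exchange_csv(curve: ACiCurve, path) -> None:
    df = pd.DataFrame(
        {
            "Ca_ppm": [r.Ca / r.Patm for r in curve.records],
            "Ci_ppm": [r.Ci / r.Patm for r in curve.records],
            "A": [r.A for r in curve.records],
            "gsw": [r.gsw for r in curve.records],
            "Tleaf": [r.Tleaf for r in curve.records],
            "Patm_bar": [r.Patm for r in curve.records],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


_ISO_COLS = [
    "Ce_ppm", "Co_ppm", "delta_e", "delta_o", "delta_vap_in", "delta_vap_out",
    "flow_umol_s", "leaf_area_m2", "Tleaf", "Patm_bar", "A", "Ci_ppm", "gsw", "E",
]


def read_isotope_csv(path) -> list[IsotopeExchangeRecord]:
    """Read an isotope-exchange table into records."""
    df = _read_csv(path, _ISO_COLS)
    try:
        return [
            IsotopeExchangeRecord(
                Ce=row.Ce_ppm,
                Co=row.Co_ppm,
                delta_e=row.delta_e,
                delta_o=row.delta_o,
                delta_vapor_in=row.delta_vap_in,
                delta_vapor_out=row.delta_vap_out,
                flow=row.flow_umol_s,
                leaf_area=row.leaf_area_m2,
                Tleaf=row.Tleaf,
                Patm=row.Patm_bar,
                A=row.A,
                Ci=row.Ci_ppm,
                gsw=row.gsw,
                E=row.E,
            )
            for row in df.itertuples()
        ]
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_isotope_csv(records: list[IsotopeExchangeRecord], path) -> None:
    df = pd.DataFrame(
        {
            "Ce_ppm": [r.Ce for r in records],
            "Co_ppm": [r.Co for r in records],
            "delta_e": [r.delta_e for r in records],
            "delta_o": [r.delta_o for r in records],
            "delta_vap_in": [r.delta_vapor_in for r in records],
            "delta_vap_out": [r.delta_vapor_out for r in records],
            "flow_umol_s": [r.flow for r in records],
            "leaf_area_m2": [r.leaf_area for r in records],
            "Tleaf": [r.Tleaf for r in records],
            "Patm_bar": [r.Patm for r in records],
            "A": [r.A for r in records],
            "Ci_ppm": [r.Ci for r in records],
            "gsw": [r.gsw for r in records],
            "E": [r.E for r in records],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace_csv(path) -> StoppedFlowTrace:
    df = _read_csv(path, ["t_s", "F"])
    try:
        return StoppedFlowTrace(t=df["t_s"].to_numpy(), F=df["F"].to_numpy())
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trace_csv(trace: StoppedFlowTrace, path) -> None:
    pd.DataFrame({"t_s": trace.t, "F": trace.F}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_plate_csv(path) -> tuple[list[GrowthCurve], list[tuple[str, str]]]:
    """Read a long-format plate table into curves and explicit pairing.

    Pairing comes from the optional ``pair_id`` column (each pair_id holds one
    treated and one untreated well); without it the returned pairing is empty
    and the caller must supply a well mapping.
    """
    df = _read_csv(path, ["well_id", "strain", "condition", "t_h", "od650"])
    curves = []
    meta = {}
    for well, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("t_h")
        cond = str(sub["condition"].iloc[0])
        if cond not in ("treated", "untreated"):
            raise ParseError(
                f"{path}: well {well}: condition must be treated/untreated, got {cond!r}"
            )
        try:
            curves.append(
                GrowthCurve(
                    t=sub["t_h"].to_numpy(),
                    od=sub["od650"].to_numpy(),
                    well_id=str(well),
                    strain=str(sub["strain"].iloc[0]),
                    condition=cond,
                )
            )
        except DomainError as exc:
            raise ParseError(f"{path}: well {well}: {exc}") from exc
        meta[str(well)] = (
            cond,
            str(sub["pair_id"].iloc[0]) if "pair_id" in sub.columns else None,
        )
    pairing: list[tuple[str, str]] = []
    if "pair_id" in df.columns:
        by_pair: dict[str, dict[str, str]] = {}
        for well, (cond, pid) in meta.items():
            by_pair.setdefault(pid, {})[cond] = well
        for pid, wells in by_pair.items():
            if set(wells) != {"treated", "untreated"}:
                raise ParseError(
                    f"{path}: pair_id {pid!r} must map exactly one treated and one "
                    f"untreated well, got {sorted(wells)}"
                )
            pairing.append((wells["treated"], wells["untreated"]))
    return curves, pairing


def write_plate_csv(
    curves: list[GrowthCurve], path, pairing: list[tuple[str, str]] | None = None
) -> None:
    pair_of = {}
    if pairing:
        for i, (tw, uw) in enumerate(pairing):
            pair_of[tw] = f"p{i}"
            pair_of[uw] = f"p{i}"
    frames = []
    for c in curves:
        frame = pd.DataFrame(
            {
                "well_id": c.well_id,
                "strain": c.strain,
                "condition": c.condition,
                "t_h": c.t,
                "od650": c.od,
            }
        )
        if pair_of:
            frame["pair_id"] = pair_of.get(c.well_id, "")
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record accompanying every analysis output."""

    command: str
    config: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    package_version: str = ""
    seed: int | None = None
    timestamp: str = ""

    @classmethod
    def create(
        cls, command: str, config: dict | None = None, inputs: list | None = None,
        seed: int | None = None,
    ) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=dict(config or {}),
            input_hashes={str(p): _sha256(p) for p in (inputs or [])},
            package_version=__version__,
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n"
        )
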