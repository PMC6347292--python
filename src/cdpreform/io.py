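"""CSV schemas, validated readers/writers and the consolidated JSON report.

Five authoritative CSV shapes move data in and out of the analysis modules:

    phase_solubility.csv  cd_conc_mmol_L, solubility_mmol_L, replicate
    dissolution.csv       formulation, medium_pH, time_min, pct_dissolved, replicate
    degradation.csv       formulation, condition, rh_pct, temp_K, time_s,
                          content_pct, replicate
    transport.csv         compound, direction, replicate, time_min,
                          receiver_conc_mg_mL
    mic.csv               organism, strain, strain_type, gram, formulation,
                          conc_mg_L, growth

Validation reports the offending file, row and column; unit sanity checks
catch Kelvin/Celsius confusion (temp_K within 250–400) and out-of-range
percentages.  Report floats are serialized with six significant digits plus a
full-precision companion field, so reports round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dissolution import DissolutionProfile
from .kinetics import DegradationSeries
from .mic import MICGrid
from .permeability import TransportSeries, WellGeometry
from .phase_solubility import PhaseSolubilityData

__all__ = [
    "SchemaError",
    "StudyConfig",
    "read_table",
    "read_phase_solubility",
    "read_dissolution",
    "read_degradation",
    "read_transport",
    "read_mic",
    "write_with_truth",
    "report_value",
    "file_digest",
    "round_trip_report",
]

log = logging.getLogger("cdpreform")


class SchemaError(ValueError):
    """A CSV file violates its schema; the message names file, row and column."""


# column name -> dtype kind ("f" float, "i" int, "s" str, "b" bool)
SCHEMAS: Dict[str, Dict[str, str]] = {
    "phase_solubility": {"cd_conc_mmol_L": "f", "solubility_mmol_L": "f", "replicate": "i"},
    "dissolution": {"formulation": "s", "medium_pH": "f", "time_min": "f",
                    "pct_dissolved": "f", "replicate": "i"},
    "degradation": {"formulation": "s", "condition": "s", "rh_pct": "f", "temp_K": "f",
                    "time_s": "f", "content_pct": "f", "replicate": "i"},
    "transport": {"compound": "s", "direction": "s", "replicate": "i",
                  "time_min": "f", "receiver_conc_mg_mL": "f"},
    "mic": {"organism": "s", "strain": "s", "strain_type": "s", "gram": "s",
            "formulation": "s", "conc_mg_L": "f", "growth": "b"},
}

# column -> (low, high, hint) inclusive unit-sanity bounds
UNIT_BOUNDS: Dict[str, Tuple[float, float, str]] = {
    "temp_K": (250.0, 400.0, "is the temperature in Kelvin, not Celsius?"),
    "pct_dissolved": (0.0, 110.0, "percent dissolved out of range"),
    "content_pct": (0.0, 110.0, "content percent out of range"),
}


@dataclass
class StudyConfig:
    """Flat key-value study configuration; unknown keys are rejected by name."""

    phase_solubility_csv: Optional[str] = None
    dissolution_csv: Optional[str] = None
    degradation_csv: Optional[str] = None
    transport_csv: Optional[str] = None
    mic_csv: Optional[str] = None
    alpha: float = 0.05
    t_ref: float = 298.0
    constant_set: str = "printed"  # "printed" | "codata"
    selection_rule: str = "plateau"  # dissolution time-point selection
    seed: int = 0
    # permeability geometry
    area_cm2: float = 0.6
    vol_apical_uL: float = 400.0
    vol_basolateral_uL: float = 600.0
    c0_mg_mL: float = 5.0
    sample_volume_uL: float = 100.0
    teer_threshold_ohm: float = 450.0

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        known = {f.name: f.type for f in dc_fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"{path}:{lineno}: expected key = value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise SchemaError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def geometry(self) -> WellGeometry:
        return WellGeometry(
            area_cm2=self.area_cm2, vol_apical_uL=self.vol_apical_uL,
            vol_basolateral_uL=self.vol_basolateral_uL, c0_mg_mL=self.c0_mg_mL,
            sample_volume_uL=self.sample_volume_uL,
            teer_threshold_ohm=self.teer_threshold_ohm,
        )


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the five named schemas.

    Numbers must use the decimal point (comma-decimal dialects are rejected
    as parse errors); diagnostics name the file, 1-based data row and column.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected header {list(spec)}"
        )
    out = {}
    for col, kind in spec.items():
        raw = df[col]
        if kind == "s":
            out[col] = raw.astype(str)
            continue
        vals = []
        for i, cell in enumerate(raw, start=1):
            cell = cell.strip()
            try:
                if kind == "f":
                    vals.append(float(cell))
                elif kind == "i":
                    vals.append(int(cell))
                else:  # bool
                    low = cell.lower()
                    if low in _TRUE:
                        vals.append(True)
                    elif low in _FALSE:
                        vals.append(False)
                    else:
                        raise ValueError(f"not a boolean: {cell!r}")
            except ValueError as exc:
                raise SchemaError(f"{path}: row {i}, column {col!r}: {exc}") from exc
        out[col] = pd.Series(vals)
        if col in UNIT_BOUNDS:
            lo, hi, hint = UNIT_BOUNDS[col]
            arr = np.asarray(vals, dtype=float)
            bad = np.nonzero((arr < lo) | (arr > hi))[0]
            if bad.size:
                i = int(bad[0]) + 1
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: value {arr[bad[0]]} outside "
                    f"[{lo}, {hi}] — {hint}"
                )
    return pd.DataFrame(out)


# ---------------------------------------------------------------- converters

def read_phase_solubility(path: str | Path) -> PhaseSolubilityData:
    """Diagram from CSV; replicates averaged per host level, units → mol/L."""
    df = read_table(path, "phase_solubility")
    g = df.groupby("cd_conc_mmol_L")["solubility_mmol_L"]
    mean = g.mean().sort_index()
    sd = g.std(ddof=1).reindex(mean.index).fillna(0.0)
    return PhaseSolubilityData(
        cd_conc=tuple(mean.index * 1e-3),
        solubility=tuple(mean.values * 1e-3),
        solubility_sd=tuple(sd.values * 1e-3),
    )


def read_dissolution(path: str | Path) -> List[DissolutionProfile]:
    """Profiles from CSV, one per (formulation, medium_pH), replicates averaged."""
    df = read_table(path, "dissolution")
    profiles = []
    for (form, ph), sub in df.groupby(["formulation", "medium_pH"]):
        mean = sub.groupby("time_min")["pct_dissolved"].mean().sort_index()
        profiles.append(DissolutionProfile(
            formulation=str(form), times=tuple(mean.index),
            pct_dissolved=tuple(mean.values), medium=f"pH {ph:g}", ph=float(ph),
        ))
    return profiles


def read_degradation(path: str | Path) -> List[DegradationSeries]:
    """Series from CSV, one per (formulation, condition, temp_K), replicates averaged."""
    df = read_table(path, "degradation")
    series = []
    for (form, cond, temp), sub in df.groupby(["formulation", "condition", "temp_K"]):
        mean = sub.groupby("time_s")["content_pct"].mean().sort_index()
        series.append(DegradationSeries(
            condition=str(cond), temperature=float(temp),
            times=tuple(mean.index), content=tuple(mean.values),
            formulation=str(form),
        ))
    return series


def read_transport(
    path: str | Path, geometry: WellGeometry, teer: Optional[Dict] = None
) -> Dict[Tuple[str, str], List[TransportSeries]]:
    """Replicate wells from CSV keyed by (compound, direction).

    ``teer`` optionally maps (compound, direction, replicate) → (pre, post) Ω.
    """
    df = read_table(path, "transport")
    wells: Dict[Tuple[str, str], List[TransportSeries]] = {}
    for (comp, direction, rep), sub in df.groupby(["compound", "direction", "replicate"]):
        sub = sub.sort_values("time_min")
        pre, post = (teer or {}).get((comp, direction, rep), (None, None))
        wells.setdefault((str(comp), str(direction)), []).append(TransportSeries(
            direction=str(direction), times=tuple(sub["time_min"]),
            receiver_conc=tuple(sub["receiver_conc_mg_mL"]),
            geometry=geometry, teer_pre=pre, teer_post=post, compound=str(comp),
        ))
    return wells


def read_mic(path: str | Path) -> Dict[str, List[MICGrid]]:
    """MIC grids from long-format CSV, keyed by formulation label."""
    df = read_table(path, "mic")
    grids: Dict[str, List[MICGrid]] = {}
    for (org, strain, stype, gram, form), sub in df.groupby(
        ["organism", "strain", "strain_type", "gram", "formulation"]
    ):
        sub = sub.sort_values("conc_mg_L")
        grids.setdefault(str(form), []).append(MICGrid(
            organism=str(org), strain=str(strain),
            concentrations=tuple(sub["conc_mg_L"]),
            growth=tuple(bool(b) for b in sub["growth"]),
            strain_type=str(stype), gram=str(gram), formulation=str(form),
        ))
    return grids


# ------------------------------------------------------------------- writers

def write_with_truth(df: pd.DataFrame, path: str | Path, truth: Dict) -> None:
    """Write a dataset CSV plus a ``<name>.truth.json`` ground-truth sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True, default=float) + "\n")
    log.info("wrote %s (%d rows) + %s", path, len(df), sidecar.name)


# -------------------------------------------------------------------- report

def report_value(x: float) -> Dict[str, object]:
    """Six-significant-digit display value plus a full-precision field."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return {"display": None if x is None else str(x), "full": None if x is None else str(x)}
    return {"display": float(f"{x:.6g}"), "full": float(np.float64(x))}


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def round_trip_report(report: Dict) -> Dict:
    """Serialize and reparse a report; used to assert lossless round-tripping."""
    return json.loads(json.dumps(report, sort_keys=True, default=float))
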