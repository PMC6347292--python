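"""Caco-2 bidirectional transport analysis: Papp, efflux ratio, TEER gating.

The apparent permeability coefficient of a compound across a cell monolayer is

    Papp = (dQ/dt) / (A · C0)        [cm s⁻¹]

where dQ/dt is the fitted linear flux of cumulative transported amount into
the receiver chamber, A the insert area and C0 the initial donor
concentration (sink conditions assumed).  Receiver sampling with buffer
replacement removes analyte at each draw, so the cumulative amount at draw j
is reconstructed as

    Q_j = C_j · V_receiver + v_sample · Σ_{i<j} C_i

The efflux ratio Papp(B→A)/Papp(A→B) > 1 suggests active efflux transport;
monolayer integrity is gated on TEER > 450 Ω (pre and post assay) by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .stats_core import DegenerateInputError, fit_line

__all__ = [
    "WellGeometry",
    "TransportSeries",
    "PappResult",
    "EffluxResult",
    "teer_gate",
    "compute_papp",
    "efflux_ratio",
    "classify_permeability",
]

#: Papp class boundaries, cm s-1; both boundaries belong to "medium".
LOW_BOUND = 1e-6
HIGH_BOUND = 1e-5


@dataclass(frozen=True)
class WellGeometry:
    """Transwell geometry and assay constants (12-well insert defaults)."""

    area_cm2: float = 0.6
    vol_apical_uL: float = 400.0
    vol_basolateral_uL: float = 600.0
    c0_mg_mL: float = 5.0
    sample_volume_uL: float = 100.0
    teer_threshold_ohm: float = 450.0

    def receiver_volume_uL(self, direction: str) -> float:
        if direction == "A->B":
            return self.vol_basolateral_uL
        if direction == "B->A":
            return self.vol_apical_uL
        raise ValueError(f"direction must be 'A->B' or 'B->A', got {direction!r}")


@dataclass(frozen=True)
class TransportSeries:
    """Receiver-chamber concentration time course for one well."""

    direction: str  # "A->B" | "B->A"
    times: Tuple[float, ...]  # min
    receiver_conc: Tuple[float, ...]  # mg mL-1
    geometry: WellGeometry = WellGeometry()
    teer_pre: Optional[float] = None  # ohm
    teer_post: Optional[float] = None
    compound: str = ""

    def __post_init__(self):
        self.geometry.receiver_volume_uL(self.direction)  # validates direction
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.receiver_conc, dtype=float)
        if t.size != c.size:
            raise ValueError("times and receiver_conc must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")


@dataclass(frozen=True)
class PappResult:
    papp: float  # cm s-1, mean across replicates
    sd: float  # cm s-1 across replicates (0 for a single well)
    direction: str
    n_replicates: int
    qc_pass: bool
    qc_reason: Optional[str] = None
    no_transport: bool = False


@dataclass(frozen=True)
class EffluxResult:
    ratio: float  # Papp(B->A)/Papp(A->B), full precision
    ratio_display: float  # rounded to 2 decimals as conventionally reported
    interpretation: str


def teer_gate(series: TransportSeries) -> Tuple[bool, Optional[str]]:
    """Monolayer-integrity gate: strict TEER > threshold pre and post assay."""
    thr = series.geometry.teer_threshold_ohm
    if series.teer_pre is None or series.teer_post is None:
        return False, "no TEER reading"
    if series.teer_pre <= thr:
        return False, f"pre-assay TEER {series.teer_pre} <= {thr} ohm"
    if series.teer_post <= thr:
        return False, f"post-assay TEER {series.teer_post} <= {thr} ohm"
    return True, None


def _papp_single(series: TransportSeries) -> Tuple[float, bool]:
    """Papp (cm/s) for one well; returns (papp, no_transport_flag)."""
    g = series.geometry
    t_s = np.asarray(series.times, dtype=float) * 60.0
    conc = np.asarray(series.receiver_conc, dtype=float)  # mg/mL == mg/cm^3
    v_r = g.receiver_volume_uL(series.direction) / 1000.0  # mL
    v_s = g.sample_volume_uL / 1000.0  # mL
    # cumulative amount, correcting for analyte removed at earlier draws (mg)
    removed = np.concatenate([[0.0], np.cumsum(conc)[:-1]]) * v_s
    q = conc * v_r + removed
    slope = fit_line(list(zip(t_s, q))).slope  # mg/s
    papp = slope / (g.area_cm2 * g.c0_mg_mL)
    if papp < 0:
        warnings.warn("negative fitted flux: no measurable transport; Papp set to 0",
                      stacklevel=3)
        return 0.0, True
    return papp, papp == 0.0


def compute_papp(replicates: Sequence[TransportSeries] | TransportSeries) -> PappResult:
    """Papp per replicate well, aggregated as mean ± SD.

    The TEER gate is evaluated first: if any replicate fails, ``qc_pass`` is
    False (the numeric result is still returned for inspection).  Needs >= 3
    time points per well.
    """
    if isinstance(replicates, TransportSeries):
        replicates = [replicates]
    if not replicates:
        raise ValueError("at least one transport series required")
    direction = replicates[0].direction
    if any(s.direction != direction for s in replicates):
        raise ValueError("all replicates must share one direction")
    for s in replicates:
        if len(s.times) < 3:
            raise DegenerateInputError("Papp flux fit needs >= 3 time points")

    qc_pass, qc_reason = True, None
    for s in replicates:
        ok, reason = teer_gate(s)
        if not ok:
            qc_pass, qc_reason = False, reason
            break

    vals, flags = zip(*(_papp_single(s) for s in replicates))
    papp = float(mean(vals))
    sd = float(stdev(vals)) if len(vals) > 1 else 0.0
    return PappResult(papp=papp, sd=sd, direction=direction,
                      n_replicates=len(vals), qc_pass=qc_pass,
                      qc_reason=qc_reason, no_transport=all(flags))


def efflux_ratio(ab: PappResult, ba: PappResult) -> EffluxResult:
    """Efflux ratio Papp(B→A)/Papp(A→B); > 2 conventionally flags active efflux."""
    if ab.papp <= 0:
        raise ZeroDivisionError("efflux ratio undefined: Papp(A->B) is zero")
    ratio = ba.papp / ab.papp
    if ratio > 2.0:
        label = "active efflux likely"
    elif ratio < 0.5:
        label = "active uptake likely"
    else:
        label = "no significant efflux"
    return EffluxResult(ratio=ratio, ratio_display=round(ratio, 2), interpretation=label)


def classify_permeability(papp: float) -> str:
    """Permeability class: low < 1e-6 <= medium <= 1e-5 < high (cm s⁻¹).

    Both band edges belong to "medium"; the classes partition [0, ∞).
    """
    if papp < 0:
        raise ValueError(f"papp must be >= 0, got {papp}")
    if papp < LOW_BOUND:
        return "low"
    if papp <= HIGH_BOUND:
        return "medium"
    return "high"
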