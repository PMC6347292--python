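"""Solid-state degradation kinetics: first-order fits, Arrhenius regression and
activation thermodynamics.

The analysis chain mirrors an accelerated stability study of a drug substance
(here: the carbapenem prodrug tebipenem pivoxil, free and as a β-cyclodextrin
inclusion complex) stored at several temperatures under a humid (RH ~76%) and a
dry (RH 0%) condition:

    content-vs-time series  →  kobs ± Δk  (ln c vs t, per condition)
                            →  Ea, ln A   (ln k vs 1/T, per humidity condition)
                            →  ΔH‡, ΔS‡   (transition-state relations at 298 K)
                            →  slope-parallelism comparison between formulations

Two internally consistent constant sets are provided.  ``PRINTED`` uses
R = 8.3144 J K⁻¹ mol⁻¹, k_B = 1.3807×10⁻²³ J K⁻¹ and h = 6.626×10⁻³⁴ J s, the
rounded values in common pharmaceutical-stability usage; ``CODATA`` uses the
exact SI values.  ΔS‡ is returned in two variants (see
:func:`activation_thermodynamics`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _st

from .stats_core import (
    DegenerateInputError,
    LinearFit,
    ParallelismResult,
    fit_line,
    parallelism_test,
)

__all__ = [
    "ConstantSet",
    "PRINTED",
    "CODATA",
    "DegradationSeries",
    "FirstOrderFit",
    "ArrheniusFit",
    "ActivationThermo",
    "fit_first_order",
    "fit_arrhenius",
    "activation_thermodynamics",
    "compare_formulations",
    "shelf_life",
]


@dataclass(frozen=True)
class ConstantSet:
    """Physical constants used by the Arrhenius/Eyring derivations."""

    R: float  # gas constant, J K-1 mol-1
    kB: float  # Boltzmann constant, J K-1
    h: float  # Planck constant, J s


PRINTED = ConstantSet(R=8.3144, kB=1.3807e-23, h=6.626e-34)
CODATA = ConstantSet(R=8.314462618, kB=1.380649e-23, h=6.62607015e-34)


@dataclass(frozen=True)
class DegradationSeries:
    """Drug content vs time at one storage condition.

    times in seconds ascending from 0; content as % of initial (any positive
    scale works — only the slope of ln(content) matters).
    """

    condition: str  # e.g. "RH76" (humid) or "RH0" (dry air)
    temperature: float  # K
    times: Tuple[float, ...]
    content: Tuple[float, ...]
    formulation: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.content, dtype=float)
        if t.size != c.size:
            raise ValueError("times and content must have equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be ascending")
        bad = np.nonzero(c <= 0)[0]
        if bad.size:
            raise ValueError(
                f"content must be positive for the log-transform; "
                f"row {bad[0]} has content {c[bad[0]]}"
            )


@dataclass(frozen=True)
class FirstOrderFit:
    """First-order rate constant from OLS of ln(content) on time.

    kobs = -slope; Δk is the confidence half-width slope_se × t(α, n−2).
    ``degrading`` is False when the fitted slope is non-negative (no
    measurable loss); kobs ≤ 0 is then reported with a warning, not an error.
    """

    kobs: float
    delta_k: float
    lnc0: float
    fit: LinearFit
    alpha: float
    degrading: bool = True


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k = ln A − Ea/(R T) fitted by OLS of ln kobs on 1/T.

    Ea = −slope × R; ea_ci is the half-width slope_se × R × t(α, n−2).
    """

    ea: float  # J mol-1
    ea_ci: float  # J mol-1
    lnA: float
    fit: LinearFit
    n_temps: int
    constants: ConstantSet = PRINTED
    alpha: float = 0.05


@dataclass(frozen=True)
class ActivationThermo:
    """Activation enthalpy and entropy at a reference temperature.

    dH = Ea − R·t_ref.  Two entropy variants are returned:

    * ``dS_standard`` — the transition-state expression
      R·(ln A − ln(k_B·t_ref/h)), the scientifically correct form;
    * ``dS_as_printed`` — −R·ln(k_B·t_ref/h), which omits the ln A term.
      Some published stability tables tabulate this lnA-independent constant
      (≈ −244.9 J K⁻¹ mol⁻¹ at 298 K) for every condition; it is exposed so
      such tables can be reproduced, but ``dS_standard`` is the default output.
    """

    t_ref: float
    dH: float  # J mol-1
    dS_standard: float  # J K-1 mol-1
    dS_as_printed: float  # J K-1 mol-1
    constants: ConstantSet = PRINTED


def fit_first_order(series: DegradationSeries, alpha: float = 0.05) -> FirstOrderFit:
    """Fit ln(content) = ln(c0) − kobs·t by ordinary least squares.

    Needs at least 3 points for a confidence half-width (with 2 points the fit
    is exact and Δk = 0).  A non-negative slope is flagged as non-degrading
    rather than raised.
    """
    t = np.asarray(series.times, dtype=float)
    c = np.asarray(series.content, dtype=float)
    if t.size < 3:
        raise DegenerateInputError("first-order fit needs >= 3 time points")
    fit = fit_line(list(zip(t, np.log(c))))
    kobs = -fit.slope
    if fit.n > 2 and fit.slope_se > 0:
        tq = float(_st.t.ppf(1.0 - alpha / 2.0, fit.n - 2))
        delta_k = fit.slope_se * tq
    else:
        delta_k = 0.0
    degrading = kobs > 0
    if not degrading:
        warnings.warn(
            f"no degradation detected (kobs = {kobs:.3g} s^-1 <= 0) for "
            f"{series.formulation or 'series'} at {series.temperature} K",
            stacklevel=2,
        )
    return FirstOrderFit(kobs=kobs, delta_k=delta_k, lnc0=fit.intercept,
                         fit=fit, alpha=alpha, degrading=degrading)


def fit_arrhenius(
    rate_constants: Sequence[Tuple[float, float]],
    constants: ConstantSet = PRINTED,
    alpha: float = 0.05,
) -> ArrheniusFit:
    """Arrhenius regression over (temperature [K], kobs [s⁻¹]) pairs.

    Requires at least 3 distinct temperatures and strictly positive rate
    constants.  Returns Ea in J mol⁻¹ (divide by 1e3 for kJ mol⁻¹).
    """
    pairs = list(rate_constants)
    temps = np.asarray([p[0] for p in pairs], dtype=float)
    ks = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(temps).size < 3:
        raise DegenerateInputError(
            f"Arrhenius fit needs >= 3 distinct temperatures, got {np.unique(temps).size}"
        )
    if np.any(ks <= 0):
        raise ValueError("all rate constants must be > 0 for the log transform")
    fit = fit_line(list(zip(1.0 / temps, np.log(ks))))
    ea = -fit.slope * constants.R
    if fit.n > 2 and fit.slope_se > 0:
        tq = float(_st.t.ppf(1.0 - alpha / 2.0, fit.n - 2))
        ea_ci = fit.slope_se * constants.R * tq
    else:
        ea_ci = 0.0
    return ArrheniusFit(ea=ea, ea_ci=ea_ci, lnA=fit.intercept, fit=fit,
                        n_temps=int(np.unique(temps).size), constants=constants,
                        alpha=alpha)


def activation_thermodynamics(
    arr: ArrheniusFit, t_ref: float = 298.0
) -> ActivationThermo:
    """Transition-state quantities at ``t_ref`` (default 298 K).

    dH = Ea − R·t_ref exactly; both entropy variants are computed (see
    :class:`ActivationThermo`).
    """
    if t_ref <= 0:
        raise ValueError(f"t_ref must be > 0 K, got {t_ref}")
    cs = arr.constants
    dH = arr.ea - cs.R * t_ref
    ln_kbt_h = math.log(cs.kB * t_ref / cs.h)
    dS_std = cs.R * (arr.lnA - ln_kbt_h)
    dS_printed = -cs.R * ln_kbt_h
    return ActivationThermo(t_ref=t_ref, dH=dH, dS_standard=dS_std,
                            dS_as_printed=dS_printed, constants=cs)


def compare_formulations(
    series_a: Sequence[DegradationSeries],
    series_b: Sequence[DegradationSeries],
    alpha: float = 0.05,
) -> Dict[Tuple[str, float], ParallelismResult]:
    """Slope-parallelism test between two formulations at matched conditions.

    Series are matched on (condition, temperature); each matched pair is
    compared on the ln(content)-vs-time scale via the pooled-variance test.
    Unmatched conditions are skipped with a warning.
    """
    index_b = {(s.condition, s.temperature): s for s in series_b}
    out: Dict[Tuple[str, float], ParallelismResult] = {}
    for sa in series_a:
        key = (sa.condition, sa.temperature)
        sb = index_b.get(key)
        if sb is None:
            warnings.warn(f"no matching series for condition {key}; skipped", stacklevel=2)
            continue
        pts_a = list(zip(sa.times, np.log(np.asarray(sa.content, dtype=float))))
        pts_b = list(zip(sb.times, np.log(np.asarray(sb.content, dtype=float))))
        out[key] = parallelism_test(pts_a, pts_b, alpha=alpha)
    return out


def shelf_life(fit: FirstOrderFit, fraction_remaining: float = 0.9) -> float:
    """Time (s) for content to fall to ``fraction_remaining`` under first-order loss.

    t = −ln(fraction)/kobs; the conventional t90 uses fraction 0.9.
    """
    if not 0 < fraction_remaining <= 1:
        raise ValueError(f"fraction_remaining must be in (0, 1], got {fraction_remaining}")
    if fit.kobs <= 0:
        raise ValueError("shelf life undefined for non-degrading series (kobs <= 0)")
    return -math.log(fraction_remaining) / fit.kobs
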