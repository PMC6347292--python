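"""Higuchi–Connors phase-solubility analysis.

The apparent solubility of a guest drug is plotted against the host
(cyclodextrin) concentration.  A linear ascending diagram with slope < 1
(A_L type) indicates 1:1 complexation, and the apparent stability constant is

    K_1:1 = slope / (S0 · (1 − slope))

with S0 the drug's intrinsic solubility.  S0 is taken from the fitted
intercept by default but can be overridden with an independently measured
value, since diagrams are sometimes fitted over a truncated linear range whose
extrapolated intercept differs from the measured intrinsic solubility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _st

from .stats_core import DegenerateInputError, LinearFit, fit_line

__all__ = [
    "PhaseSolubilityData",
    "PhaseSolubilityFit",
    "fit_phase_solubility",
    "classify_diagram",
]


@dataclass(frozen=True)
class PhaseSolubilityData:
    """Phase-solubility diagram points (host concentration vs guest solubility).

    Both axes in mol L⁻¹.  Replicates at the same host level should be
    averaged before construction; per-level SDs may be carried as metadata.
    """

    cd_conc: Tuple[float, ...]
    solubility: Tuple[float, ...]
    medium: str = "water"
    solubility_sd: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        cd = np.asarray(self.cd_conc, dtype=float)
        s = np.asarray(self.solubility, dtype=float)
        if cd.size != s.size or cd.size < 3:
            raise ValueError("need equal-length cd_conc/solubility with >= 3 points")
        if np.any(cd < 0):
            raise ValueError("cd_conc must be nonnegative")
        if np.any(np.diff(cd) <= 0):
            raise ValueError("cd_conc must be strictly increasing (aggregate replicates first)")


@dataclass(frozen=True)
class PhaseSolubilityFit:
    """Fitted diagram: slope (dimensionless), S0 (mol L⁻¹) and K1:1 (L mol⁻¹).

    ``k11`` is None when undefined (slope outside (0, 1) or S0 <= 0);
    ``k11_undefined_reason`` then says why.  slope == 0 gives k11 = 0.
    """

    fit: LinearFit
    s0: float
    k11: Optional[float]
    diagram_class: str  # "A_L" | "nonlinear" | "descending"
    linear_range: Tuple[float, float]
    k11_undefined_reason: Optional[str] = None


def fit_phase_solubility(
    data: PhaseSolubilityData,
    s0_override: Optional[float] = None,
    linear_range: Optional[Tuple[float, float]] = None,
) -> PhaseSolubilityFit:
    """OLS fit of the diagram (over ``linear_range`` if given) and K1:1.

    K1:1 = slope/(S0·(1−slope)) in L mol⁻¹, defined for 0 ≤ slope < 1 and
    S0 > 0 (slope 0 gives K1:1 = 0); otherwise the constant is reported as
    undefined with a reason rather than raising.
    """
    cd = np.asarray(data.cd_conc, dtype=float)
    s = np.asarray(data.solubility, dtype=float)
    if linear_range is not None:
        lo, hi = linear_range
        mask = (cd >= lo) & (cd <= hi)
        if mask.sum() < 3:
            raise DegenerateInputError(
                f"linear range {linear_range} contains {int(mask.sum())} points; need >= 3"
            )
        cd, s = cd[mask], s[mask]
        rng = (float(lo), float(hi))
    else:
        rng = (float(cd[0]), float(cd[-1]))

    fit = fit_line(list(zip(cd, s)))
    s0 = float(s0_override) if s0_override is not None else fit.intercept

    k11: Optional[float]
    reason: Optional[str] = None
    if fit.slope >= 1.0:
        k11, reason = None, f"slope {fit.slope:.4g} >= 1: outside the A_L domain"
    elif fit.slope < 0.0:
        k11, reason = None, f"slope {fit.slope:.4g} < 0: descending diagram"
    elif s0 <= 0.0:
        k11, reason = None, f"S0 {s0:.4g} <= 0: intrinsic solubility must be positive"
    elif fit.slope == 0.0:
        k11 = 0.0
    else:
        k11 = fit.slope / (s0 * (1.0 - fit.slope))

    if fit.slope > 0:
        cls = "A_L"
    elif fit.slope < 0:
        cls = "descending"
    else:
        cls = "nonlinear"
    return PhaseSolubilityFit(fit=fit, s0=s0, k11=k11, diagram_class=cls,
                              linear_range=rng, k11_undefined_reason=reason)


def _linearity_pvalue(cd: np.ndarray, s: np.ndarray) -> float:
    """P-value of an F-test for curvature: does a quadratic term improve the fit?

    Used as the lack-of-fit criterion when replicate pure error is unavailable
    (the diagram has one averaged point per host level).
    """
    n = cd.size
    if n < 4:
        return 1.0
    X1 = np.column_stack([np.ones(n), cd])
    X2 = np.column_stack([np.ones(n), cd, cd**2])
    rss1 = float(np.sum((s - X1 @ np.linalg.lstsq(X1, s, rcond=None)[0]) ** 2))
    rss2 = float(np.sum((s - X2 @ np.linalg.lstsq(X2, s, rcond=None)[0]) ** 2))
    df2 = n - 3
    if rss2 <= 0:
        # quadratic fits exactly; any leftover linear residual means curvature
        return 0.0 if rss1 > 1e-12 * max(1.0, float(np.sum(s**2))) else 1.0
    f = (rss1 - rss2) / (rss2 / df2)
    return float(_st.f.sf(f, 1, df2))


def classify_diagram(
    data: PhaseSolubilityData, alpha: float = 0.05
) -> Tuple[str, Tuple[float, float]]:
    """Classify the diagram and report its widest linear prefix.

    Starting from the full diagram and shrinking from the right, the widest
    prefix (>= 4 points) on which linearity is not rejected (curvature F-test
    at ``alpha``) is reported.  Ascending linear prefix → "A_L"; monotone
    decreasing → "descending"; otherwise "nonlinear".
    """
    cd = np.asarray(data.cd_conc, dtype=float)
    s = np.asarray(data.solubility, dtype=float)
    if cd.size < 4:
        raise DegenerateInputError("classification needs >= 4 points")

    if np.all(np.diff(s) < 0):
        return "descending", (float(cd[0]), float(cd[-1]))

    for m in range(cd.size, 3, -1):
        if _linearity_pvalue(cd[:m], s[:m]) >= alpha:
            slope = fit_line(list(zip(cd[:m], s[:m]))).slope
            if slope > 0:
                return "A_L", (float(cd[0]), float(cd[m - 1]))
            if slope < 0:
                return "descending", (float(cd[0]), float(cd[m - 1]))
            break
    return "nonlinear", (float(cd[0]), float(cd[-1]))
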