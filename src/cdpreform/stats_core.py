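"""Shared least-squares machinery, slope-parallelism testing and calibration metrics.

Everything downstream — first-order degradation fits, Arrhenius regressions,
phase-solubility diagrams, flux slopes — runs through :func:`fit_line`, so the
standard errors and the pooled-variance parallelism test live here in one place.
All fits are ordinary (unweighted) least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _st

__all__ = [
    "LinearFit",
    "ParallelismResult",
    "CalibrationResult",
    "DegenerateInputError",
    "fit_line",
    "parallelism_test",
    "calibrate",
]


class DegenerateInputError(ValueError):
    """Raised when a regression design is degenerate (e.g. a single distinct x)."""


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line y = slope*x + intercept.

    ``slope_se``/``intercept_se`` are computed from the residual variance with
    n - 2 degrees of freedom; for an exact two-point fit both are zero.
    ``r`` is the Pearson correlation of the fitted points.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r: float
    n: int
    residual_ss: float
    #: sum of squared deviations of x about its mean (Sxx); needed by the
    #: parallelism test's pooled slope-difference standard error.
    sxx: float = float("nan")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class ParallelismResult:
    """Student-type test of equality of two regression slopes.

    t0 = (a1 - a2) / S_{a1-a2} with the pooled residual variance of both
    regressions on n1 + n2 - 4 degrees of freedom.  ``exact_separation`` flags
    the degenerate noise-free limit: both fits perfect but slopes differ, in
    which case t0 is +/-inf and the difference is reported as significant.
    """

    t0: float
    df: int
    t_critical: float
    alpha: float
    significant: bool
    slope_diff: float
    slope_diff_se: float
    exact_separation: bool = False


@dataclass(frozen=True)
class CalibrationResult:
    """Calibration-line validation metrics: LOD = 3 SD/a and LOQ = 10 SD/a.

    SD is the averaged standard deviation of determinations in the lower range
    of linearity and a the calibration slope; LOQ/LOD = 10/3 by construction.
    """

    fit: LinearFit
    lod: float
    loq: float
    recovery_pct: Optional[float] = None
    rsd_pct: Optional[float] = None


def _as_xy(points: Sequence[Tuple[float, float]], name: str = "points"):
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateInputError(f"{name}: need >= 2 (x, y) pairs, got shape {arr.shape}")
    return arr[:, 0], arr[:, 1]


def fit_line(points: Sequence[Tuple[float, float]]) -> LinearFit:
    """Ordinary least-squares fit of a straight line to (x, y) pairs.

    Raises :class:`DegenerateInputError` when fewer than two distinct x values
    are supplied.  With exactly two points the fit is exact and both standard
    errors are zero.
    """
    x, y = _as_xy(points)
    if np.unique(x).size < 2:
        raise DegenerateInputError("x: fewer than 2 distinct values — slope undefined")

    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    rss = float(resid @ resid)

    syy = float(np.sum((y - ybar) ** 2))
    if syy > 0:
        r = sxy / math.sqrt(sxx * syy)
        r = max(-1.0, min(1.0, r))
    else:
        r = 0.0  # flat response: correlation undefined, report 0

    if n > 2:
        s2 = rss / (n - 2)
        slope_se = math.sqrt(s2 / sxx)
        intercept_se = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    else:
        rss = 0.0
        slope_se = 0.0
        intercept_se = 0.0

    return LinearFit(slope, intercept, slope_se, intercept_se, r, int(n), rss, sxx=sxx)


def parallelism_test(
    series1: Sequence[Tuple[float, float]],
    series2: Sequence[Tuple[float, float]],
    alpha: float = 0.05,
) -> ParallelismResult:
    """Test whether two regression slopes differ (two-sided), pooling residuals.

    The slope-difference standard error pools the residual sums of squares of
    both regressions over n1 + n2 - 4 degrees of freedom and multiplies by the
    sum of reciprocal x sums-of-squares:

        S^2 = (RSS1 + RSS2)/(n1 + n2 - 4) * (1/Sxx1 + 1/Sxx2)

    When both regressions are exact (zero residuals) but the slopes differ, the
    statistic diverges; that limit is reported as ``exact_separation`` with
    t0 = +/-inf and ``significant=True`` instead of raising, because noise-free
    synthetic inputs are a supported path.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    f1 = fit_line(series1)
    f2 = fit_line(series2)
    df = f1.n + f2.n - 4
    if df < 1:
        raise DegenerateInputError(
            f"parallelism test needs n1 + n2 - 4 >= 1 degrees of freedom, got {df}"
        )
    pooled = (f1.residual_ss + f2.residual_ss) / df
    se = math.sqrt(pooled * (1.0 / f1.sxx + 1.0 / f2.sxx))
    diff = f1.slope - f2.slope
    t_crit = float(_st.t.ppf(1.0 - alpha / 2.0, df))

    # zero residual variance up to float round-off of two exact fits
    if se <= 1e-10 * max(abs(f1.slope), abs(f2.slope)):
        if diff == 0.0:
            return ParallelismResult(0.0, df, t_crit, alpha, False, diff, 0.0)
        # slopes differ with zero residual variance
        return ParallelismResult(
            math.copysign(math.inf, diff), df, t_crit, alpha, True, diff, 0.0,
            exact_separation=True,
        )
    t0 = diff / se
    return ParallelismResult(t0, df, t_crit, alpha, abs(t0) > t_crit, diff, se)


def calibrate(
    points: Sequence[Tuple[float, float]],
    low_range_sd: float,
    replicates: Optional[Sequence[float]] = None,
    nominal: Optional[float] = None,
) -> CalibrationResult:
    """Validation metrics for a calibration line.

    lod = 3 SD / |a| and loq = 10 SD / |a|, where ``low_range_sd`` is the
    averaged standard deviation of determinations in the lower linearity range
    and a the fitted slope.  When replicate determinations (and optionally
    their nominal concentration) are supplied, precision (RSD %) and accuracy
    (recovery %) are computed from them.
    """
    if low_range_sd < 0:
        raise ValueError(f"low_range_sd must be >= 0, got {low_range_sd}")
    fit = fit_line(points)
    if fit.slope == 0.0:
        raise ZeroDivisionError("calibration slope is zero — LOD undefined")
    a = abs(fit.slope)
    lod = 3.0 * low_range_sd / a
    loq = 10.0 * low_range_sd / a

    recovery = rsd = None
    if replicates is not None:
        rep = np.asarray(replicates, dtype=float)
        mean = float(rep.mean())
        if mean != 0.0:
            rsd = float(rep.std(ddof=1) / mean * 100.0) if rep.size > 1 else 0.0
        if nominal is not None and nominal != 0.0:
            recovery = mean / float(nominal) * 100.0
    return CalibrationResult(fit=fit, lod=lod, loq=loq, recovery_pct=recovery, rsd_pct=rsd)
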