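"""Dissolution-profile comparison via the Moore–Flanner f1/f2 factors.

f1 (difference factor) and f2 (similarity factor) compare a test release curve
against a reference point-by-point over common withdrawal times:

    f1 = Σ|Rj − Tj| / ΣRj × 100
    f2 = 50 · log10( 100 / sqrt(1 + (1/n)·Σ(Rj − Tj)²) )

Identical profiles give f1 = 0 and f2 = 100; f2 ≥ 50 is the conventional
similarity band (an average point-wise gap of ≤ 10%).  f1 is intentionally
asymmetric in (reference, test): its denominator is the reference curve.

A serial-sampling correction is provided for paddle-apparatus runs where each
withdrawn aliquot is replaced with fresh medium, which dilutes later samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DissolutionProfile",
    "SimilarityResult",
    "ProfileAlignmentError",
    "select_timepoints",
    "compute_f1_f2",
    "correct_for_sampling",
]

#: Regulatory plateau convention: points after both profiles first exceed this
#: % dissolved carry no discriminating information and are dropped (keeping one).
PLATEAU_CUTOFF_PCT = 85.0


class ProfileAlignmentError(ValueError):
    """Raised when two profiles share no usable common time points."""


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative % dissolved vs time for one formulation in one medium.

    Replicates are averaged per time point before comparison.
    """

    formulation: str
    times: Tuple[float, ...]  # min
    pct_dissolved: Tuple[float, ...]
    medium: str = ""
    ph: Optional[float] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pct_dissolved, dtype=float)
        if t.size != p.size or t.size == 0:
            raise ValueError("times and pct_dissolved must be equal-length and nonempty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")


@dataclass(frozen=True)
class SimilarityResult:
    f1: float
    f2: float
    n_used: int
    points_used: Tuple[float, ...]
    verdict: str  # "similar" | "dissimilar" | "borderline"


def select_timepoints(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    rule: str = "plateau",
) -> List[float]:
    """Common withdrawal times of two profiles, truncated by ``rule``.

    "all" keeps the full intersection of the two time grids; "plateau"
    additionally drops points after both profiles first exceed 85% dissolved,
    keeping at most one such point.
    """
    if rule not in ("plateau", "all"):
        raise ValueError(f"unknown selection rule {rule!r}; use 'plateau' or 'all'")
    common = sorted(set(reference.times) & set(test.times))
    if rule == "all" or not common:
        return common
    r = dict(zip(reference.times, reference.pct_dissolved))
    t = dict(zip(test.times, test.pct_dissolved))
    kept: List[float] = []
    for tp in common:
        kept.append(tp)
        if r[tp] > PLATEAU_CUTOFF_PCT and t[tp] > PLATEAU_CUTOFF_PCT:
            break
    return kept


def compute_f1_f2(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    selection_rule: str = "plateau",
    strict: bool = False,
) -> SimilarityResult:
    """Moore–Flanner comparison over the selected common time points.

    Verdict: "similar" when f2 ∈ [50, 100] (strict mode additionally requires
    f1 ≤ 15, reporting "borderline" when f2 passes but f1 does not);
    "dissimilar" when f2 < 50.
    """
    pts = select_timepoints(reference, test, selection_rule)
    if len(pts) < 3:
        raise ProfileAlignmentError(
            f"profiles share {len(pts)} usable time points after selection; need >= 3"
        )
    r = np.asarray([dict(zip(reference.times, reference.pct_dissolved))[t] for t in pts])
    t_ = np.asarray([dict(zip(test.times, test.pct_dissolved))[t] for t in pts])
    sum_r = float(r.sum())
    if sum_r <= 0:
        raise ValueError("reference profile sums to zero over selected points; f1 undefined")
    f1 = float(np.abs(r - t_).sum() / sum_r * 100.0)
    msd = float(np.mean((r - t_) ** 2))
    f2 = 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))

    if f2 < 50.0:
        verdict = "dissimilar"
    elif strict and f1 > 15.0:
        verdict = "borderline"
    else:
        verdict = "similar"
    return SimilarityResult(f1=f1, f2=f2, n_used=len(pts),
                            points_used=tuple(pts), verdict=verdict)


def correct_for_sampling(
    profile: DissolutionProfile,
    sample_volume_mL: float,
    vessel_volume_mL: float,
) -> DissolutionProfile:
    """Correct cumulative % dissolved for analyte removed at earlier withdrawals.

    With replacement of each withdrawn aliquot by fresh medium, the measured
    value at draw j underestimates the cumulative release by the analyte
    carried out in draws 1..j−1:

        corrected_j = measured_j + (v/V) · Σ_{i<j} measured_i

    The formula applies equally to concentrations and to the proportional
    %-dissolved scale used here.
    """
    if not 0 <= sample_volume_mL < vessel_volume_mL:
        raise ValueError("need 0 <= sample_volume < vessel_volume")
    frac = sample_volume_mL / vessel_volume_mL
    measured = np.asarray(profile.pct_dissolved, dtype=float)
    corrected = measured + frac * np.concatenate([[0.0], np.cumsum(measured)[:-1]])
    return replace(profile, pct_dissolved=tuple(float(v) for v in corrected))
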