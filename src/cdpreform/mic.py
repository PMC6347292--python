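"""MIC determination from broth-dilution growth grids and formulation comparison.

The minimal inhibitory concentration is the lowest tested concentration that
prevents visible growth, provided every higher concentration is also
growth-free.  Grids need not be exact two-fold ladders (published tables often
round, e.g. 31/62/125 mg L⁻¹).  Censoring: growth at every concentration →
"> max tested"; no growth anywhere → "≤ min tested".

Comparison between a free drug and its complexed form reports per-strain fold
change MIC_free/MIC_complex (> 1 means the complex is more potent) with
Gram-group summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MICGrid",
    "MICValue",
    "MICComparison",
    "ComparisonSummary",
    "determine_mic",
    "compare_mic_tables",
    "compare_wide_table",
]

CENSOR_EXACT = "exact"
CENSOR_LE_MIN = "<=min"
CENSOR_GT_MAX = ">max"


@dataclass(frozen=True)
class MICGrid:
    """Growth/no-growth outcomes across a monotone dilution series for one strain."""

    organism: str
    strain: str
    concentrations: Tuple[float, ...]  # mg L-1
    growth: Tuple[bool, ...]
    strain_type: str = "clinical"  # "clinical" | "reference"
    gram: str = ""  # "positive" | "negative"
    formulation: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.size != len(self.growth) or c.size < 2:
            raise ValueError("need >= 2 concentrations with matching growth flags")
        d = np.diff(c)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("concentrations must be strictly monotone")


@dataclass(frozen=True)
class MICValue:
    mic: float  # mg L-1 (boundary value when censored)
    censoring: str  # CENSOR_EXACT | CENSOR_LE_MIN | CENSOR_GT_MAX
    skipped_well: bool = False  # non-monotone growth pattern encountered

    def __str__(self) -> str:
        if self.censoring == CENSOR_LE_MIN:
            return f"<={self.mic:g}"
        if self.censoring == CENSOR_GT_MAX:
            return f">{self.mic:g}"
        return f"{self.mic:g}"


@dataclass(frozen=True)
class MICComparison:
    organism: str
    strain: str
    gram: str
    mic_ref: MICValue
    mic_test: MICValue
    fold_change: Optional[float]  # mic_ref/mic_test; None if either censored
    log2_fold_change: Optional[float]
    reduced: Optional[bool]  # mic_test < mic_ref; None if not comparable


@dataclass(frozen=True)
class ComparisonSummary:
    n_compared: int
    n_reduced: int
    n_unchanged: int
    n_increased: int
    by_gram: Dict[str, Dict[str, int]]
    unmatched_ref: Tuple[Tuple[str, str], ...]
    unmatched_test: Tuple[Tuple[str, str], ...]


def determine_mic(grid: MICGrid) -> MICValue:
    """MIC of one grid: lowest concentration opening an unbroken growth-free suffix.

    Skipped wells (growth above a growth-free concentration) are flagged and
    the MIC taken at the start of the highest clean suffix, with a warning.
    """
    conc = np.asarray(grid.concentrations, dtype=float)
    grow = np.asarray(grid.growth, dtype=bool)
    order = np.argsort(conc)
    conc, grow = conc[order], grow[order]

    if grow.all():
        return MICValue(mic=float(conc[-1]), censoring=CENSOR_GT_MAX)
    if not grow.any():
        return MICValue(mic=float(conc[0]), censoring=CENSOR_LE_MIN)

    last_growth = int(np.max(np.nonzero(grow)[0]))
    # clean suffix starts right after the highest growth-positive well
    suffix_start = last_growth + 1
    if suffix_start >= conc.size:  # growth at the top well but not everywhere
        return MICValue(mic=float(conc[-1]), censoring=CENSOR_GT_MAX,
                        skipped_well=bool(np.any(~grow[:last_growth])))
    skipped = bool(np.any(~grow[:suffix_start]))
    if skipped:
        warnings.warn(
            f"{grid.organism} {grid.strain}: non-monotone growth pattern "
            f"(skipped well); MIC taken at the highest clean suffix",
            stacklevel=2,
        )
    return MICValue(mic=float(conc[suffix_start]), censoring=CENSOR_EXACT,
                    skipped_well=skipped)


def _compare_pair(ref: MICValue, test: MICValue, organism: str, strain: str,
                  gram: str) -> MICComparison:
    if ref.censoring == CENSOR_EXACT and test.censoring == CENSOR_EXACT:
        fc = ref.mic / test.mic
        return MICComparison(organism, strain, gram, ref, test,
                             fold_change=fc, log2_fold_change=math.log2(fc),
                             reduced=test.mic < ref.mic)
    return MICComparison(organism, strain, gram, ref, test,
                         fold_change=None, log2_fold_change=None, reduced=None)


def compare_mic_tables(
    free_grids: Sequence[MICGrid],
    complex_grids: Sequence[MICGrid],
) -> Tuple[List[MICComparison], ComparisonSummary]:
    """Per-strain MIC fold changes between two formulations.

    Strains are matched on (organism, strain); unmatched entries are listed in
    the summary, never dropped silently.
    """
    ref_mics = {(g.organism, g.strain): (determine_mic(g), g) for g in free_grids}
    test_mics = {(g.organism, g.strain): (determine_mic(g), g) for g in complex_grids}

    comparisons: List[MICComparison] = []
    for key in ref_mics:
        if key in test_mics:
            (rv, rg), (tv, _) = ref_mics[key], test_mics[key]
            comparisons.append(_compare_pair(rv, tv, key[0], key[1], rg.gram))
    unmatched_ref = tuple(k for k in ref_mics if k not in test_mics)
    unmatched_test = tuple(k for k in test_mics if k not in ref_mics)
    return comparisons, summarize(comparisons, unmatched_ref, unmatched_test)


def compare_wide_table(
    rows: Sequence[dict],
) -> Tuple[List[MICComparison], ComparisonSummary]:
    """Comparison from a wide table of already-determined MICs.

    Each row: organism, strain (or strain_type), gram, mic_free, mic_complex
    (mg L⁻¹, exact values).
    """
    comparisons = []
    for row in rows:
        ref = MICValue(mic=float(row["mic_free"]), censoring=CENSOR_EXACT)
        test = MICValue(mic=float(row["mic_complex"]), censoring=CENSOR_EXACT)
        comparisons.append(_compare_pair(
            ref, test, str(row["organism"]),
            str(row.get("strain", row.get("strain_type", ""))),
            str(row.get("gram", "")),
        ))
    return comparisons, summarize(comparisons, (), ())


def summarize(
    comparisons: Sequence[MICComparison],
    unmatched_ref: Tuple[Tuple[str, str], ...] = (),
    unmatched_test: Tuple[Tuple[str, str], ...] = (),
) -> ComparisonSummary:
    by_gram: Dict[str, Dict[str, int]] = {}
    n_red = n_unch = n_inc = 0
    for c in comparisons:
        g = by_gram.setdefault(c.gram or "unknown",
                               {"reduced": 0, "unchanged": 0, "increased": 0})
        if c.reduced is None:
            continue
        if c.reduced:
            n_red += 1
            g["reduced"] += 1
        elif c.fold_change is not None and c.fold_change < 1:
            n_inc += 1
            g["increased"] += 1
        else:
            n_unch += 1
            g["unchanged"] += 1
    return ComparisonSummary(
        n_compared=len(comparisons), n_reduced=n_red, n_unchanged=n_unch,
        n_increased=n_inc, by_gram=by_gram,
        unmatched_ref=unmatched_ref, unmatched_test=unmatched_test,
    )
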