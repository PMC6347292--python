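"""Synthetic datasets with known ground truth for every analysis stage.

Five generators emulate the data shapes of a cyclodextrin preformulation
study — A_L-type phase-solubility diagrams, saturating dissolution curves,
first-order degradation series obeying an Arrhenius law, sink-condition
bidirectional transport time courses, and two-fold-dilution MIC grids — each
returning the dataset together with the ground-truth parameters that produced
it, so recovery tests are self-contained.

Measurement noise is multiplicative Gaussian on the measured quantity
(an assay-CV model), with the noise factor truncated at zero so values stay
nonnegative.  One global seed drives everything; each scenario draws from a
deterministic substream, so identical seed + parameters give identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .dissolution import DissolutionProfile
from .kinetics import PRINTED, ConstantSet, DegradationSeries
from .mic import MICGrid
from .permeability import TransportSeries, WellGeometry
from .phase_solubility import PhaseSolubilityData

__all__ = [
    "SimulationConfig",
    "make_phase_solubility",
    "make_dissolution",
    "make_degradation",
    "make_transport",
    "make_mic_grid",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Global knobs shared by all generators.

    noise_cv is the coefficient of variation of the multiplicative Gaussian
    measurement noise (0.02 ≈ a well-behaved HPLC assay); replicates is the
    number of independent measurement replicates where the design has them.
    """

    seed: int = 0
    noise_cv: float = 0.0
    replicates: int = 3

    def rng(self, scenario: str) -> np.random.Generator:
        """Deterministic per-scenario substream of the global seed."""
        return np.random.default_rng([self.seed, zlib.crc32(scenario.encode())])


def _noisy(values: np.ndarray, rng: np.random.Generator, cv: float) -> np.ndarray:
    """Multiplicative Gaussian noise, factor truncated at 0 (nonnegative data)."""
    if cv == 0.0:
        return values.copy()
    factor = np.maximum(0.0, 1.0 + cv * rng.standard_normal(values.shape))
    return values * factor


class PhaseSolubilitySim(NamedTuple):
    data: PhaseSolubilityData
    truth: Dict[str, float]


def make_phase_solubility(
    s0: float,
    k11: float,
    cd_grid: Sequence[float] = tuple(x * 1e-3 for x in (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)),
    cfg: SimulationConfig = SimulationConfig(),
) -> PhaseSolubilitySim:
    """A_L-type diagram: S_t = s0 + slope·[CD], slope = k11·s0/(1 + k11·s0).

    Default host grid: 7 levels, 0–3 mmol L⁻¹ (the linear range of a typical
    diagram).  All concentrations in mol L⁻¹.  Replicates are averaged into
    the returned diagram, with per-level SD carried as metadata.
    """
    if s0 <= 0:
        raise ValueError(f"s0 must be > 0, got {s0}")
    if k11 < 0:
        raise ValueError(f"k11 must be >= 0, got {k11}")
    cd = np.asarray(cd_grid, dtype=float)
    if np.any(cd < 0) or np.any(np.diff(cd) <= 0):
        raise ValueError("cd_grid must be nonnegative and strictly ascending")
    slope = k11 * s0 / (1.0 + k11 * s0)
    true_s = s0 + slope * cd
    rng = cfg.rng("phase_solubility")
    reps = np.stack([_noisy(true_s, rng, cfg.noise_cv) for _ in range(cfg.replicates)])
    mean_s = reps.mean(axis=0)
    sd_s = reps.std(axis=0, ddof=1) if cfg.replicates > 1 else np.zeros_like(mean_s)
    data = PhaseSolubilityData(
        cd_conc=tuple(cd), solubility=tuple(mean_s),
        solubility_sd=tuple(sd_s), medium="water",
    )
    return PhaseSolubilitySim(data, {"s0": s0, "k11": k11, "slope": slope})


class DissolutionSim(NamedTuple):
    profile: DissolutionProfile
    truth: Dict[str, float]


def make_dissolution(
    plateau_pct: float,
    rate: float,
    times: Sequence[float] = (5, 10, 15, 20, 30, 45, 60),
    cfg: SimulationConfig = SimulationConfig(),
    formulation: str = "test",
    medium: str = "water",
    sampling_correction: Optional[Tuple[float, float]] = None,
) -> DissolutionSim:
    """Saturating release curve %(t) = plateau·(1 − e^(−rate·t)), clipped to [0, 100].

    ``sampling_correction=(v_mL, V_mL)`` applies the serial-sampling dilution
    in *reverse*: the emitted values are what an analyst would measure after
    each withdrawal-with-replacement, so that
    :func:`cdpreform.dissolution.correct_for_sampling` recovers the true curve.
    """
    if not 0 < plateau_pct <= 100:
        raise ValueError(f"plateau_pct must be in (0, 100], got {plateau_pct}")
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    t = np.asarray(times, dtype=float)
    true_pct = plateau_pct * (1.0 - np.exp(-rate * t))
    rng = cfg.rng(f"dissolution:{formulation}:{medium}")
    reps = np.stack([
        np.clip(_noisy(true_pct, rng, cfg.noise_cv), 0.0, 100.0)
        for _ in range(cfg.replicates)
    ])
    pct = reps.mean(axis=0)
    if sampling_correction is not None:
        v, vv = sampling_correction
        frac = v / vv
        measured = np.empty_like(pct)
        acc = 0.0  # running sum of earlier measured values
        for j, target in enumerate(pct):
            measured[j] = target - frac * acc
            acc += measured[j]
        pct = measured
    profile = DissolutionProfile(formulation=formulation, times=tuple(t),
                                 pct_dissolved=tuple(pct), medium=medium)
    return DissolutionSim(profile, {"plateau_pct": plateau_pct, "rate": rate})


class DegradationSim(NamedTuple):
    series: List[DegradationSeries]
    truth: Dict[str, object]


def make_degradation(
    ea: float,
    lnA: float,
    temps: Sequence[float] = (303.0, 313.0, 323.0, 333.0),
    times: Optional[Sequence[float]] = None,
    c0: float = 100.0,
    cfg: SimulationConfig = SimulationConfig(),
    condition: str = "RH76",
    formulation: str = "drug",
    constants: ConstantSet = PRINTED,
) -> DegradationSim:
    """First-order decay series at several temperatures under one Arrhenius law.

    k(T) = exp(lnA − Ea/(R·T)); c(t) = c0·e^(−k·t) with multiplicative noise.
    Ea in J mol⁻¹, times in seconds.  Default design: 4 temperatures × 12
    sampling points (the sampling density implied by f = 10 regression degrees
    of freedom in published stability tables), spanning roughly two half-lives
    at the slowest temperature.
    """
    temps = np.asarray(temps, dtype=float)
    if np.any((temps < 250) | (temps > 400)):
        raise ValueError("temperatures must lie within 250-400 K")
    ks = np.exp(lnA - ea / (constants.R * temps))
    if times is None:
        # 12 points from 0 to ~2 half-lives of the slowest series
        horizon = 2.0 * np.log(2.0) / ks.min()
        times = np.linspace(0.0, horizon, 12)
    t = np.asarray(times, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must ascend from 0")
    rng = cfg.rng(f"degradation:{formulation}:{condition}")
    series = []
    for temp, k in zip(temps, ks):
        content = _noisy(c0 * np.exp(-k * t), rng, cfg.noise_cv)
        series.append(DegradationSeries(condition=condition, temperature=float(temp),
                                        times=tuple(t), content=tuple(content),
                                        formulation=formulation))
    truth = {"ea": ea, "lnA": lnA, "c0": c0,
             "k_by_temp": {float(T): float(k) for T, k in zip(temps, ks)}}
    return DegradationSim(series, truth)


class TransportSim(NamedTuple):
    ab: TransportSeries
    ba: TransportSeries
    truth: Dict[str, float]


def make_transport(
    papp_ab: float,
    papp_ba: float,
    geometry: WellGeometry = WellGeometry(),
    times: Sequence[float] = (15, 30, 60, 90, 120),
    cfg: SimulationConfig = SimulationConfig(),
    compound: str = "drug",
    teer: Tuple[float, float] = (520.0, 495.0),
) -> TransportSim:
    """Sink-condition bidirectional transport: Q(t) = Papp·A·C0·t in the receiver.

    The receiver concentration honours sampling-with-replacement dilution at
    each draw, so the analyzer's cumulative-amount reconstruction inverts it
    exactly.  Papp in cm s⁻¹, times in minutes.
    """
    if papp_ab < 0 or papp_ba < 0:
        raise ValueError("Papp values must be >= 0")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly ascending")
    rng = cfg.rng("transport:" + compound)

    def one_direction(papp: float, direction: str) -> TransportSeries:
        v_r = geometry.receiver_volume_uL(direction) / 1000.0  # mL
        v_s = geometry.sample_volume_uL / 1000.0
        q_true = papp * geometry.area_cm2 * geometry.c0_mg_mL * (t * 60.0)  # mg
        conc = np.empty_like(q_true)
        removed = 0.0  # mg carried out by earlier draws
        for j, q in enumerate(q_true):
            conc[j] = (q - removed) / v_r
            removed += conc[j] * v_s
        conc = _noisy(conc, rng, cfg.noise_cv)
        return TransportSeries(direction=direction, times=tuple(t),
                               receiver_conc=tuple(conc), geometry=geometry,
                               teer_pre=teer[0], teer_post=teer[1],
                               compound=compound)

    return TransportSim(
        ab=one_direction(papp_ab, "A->B"),
        ba=one_direction(papp_ba, "B->A"),
        truth={"papp_ab": papp_ab, "papp_ba": papp_ba},
    )


class MICSim(NamedTuple):
    grid: MICGrid
    truth: Dict[str, float]


def make_mic_grid(
    true_mic: float,
    dilution_series: Sequence[float] = (0.5, 1, 2, 4, 8, 16, 32, 64, 128, 256),
    cfg: SimulationConfig = SimulationConfig(),
    organism: str = "organism",
    strain: str = "strain",
    misclassification_p: float = 0.0,
    **grid_kwargs,
) -> MICSim:
    """Dilution growth grid: growth exactly at concentrations below the true MIC.

    Deterministic by default; ``misclassification_p`` flips each well
    independently for robustness testing.
    """
    if true_mic <= 0:
        raise ValueError(f"true_mic must be > 0, got {true_mic}")
    conc = np.asarray(dilution_series, dtype=float)
    d = np.diff(conc)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("dilution_series must be strictly monotone")
    growth = conc < true_mic
    if misclassification_p > 0:
        rng = cfg.rng(f"mic:{organism}:{strain}")
        flips = rng.random(conc.size) < misclassification_p
        growth = growth ^ flips
    grid = MICGrid(organism=organism, strain=strain,
                   concentrations=tuple(conc), growth=tuple(bool(g) for g in growth),
                   **grid_kwargs)
    return MICSim(grid, {"true_mic": true_mic})
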