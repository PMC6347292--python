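"""Degradation kinetics chain: first-order fits, Arrhenius, activation thermo."""

import math
import warnings

import numpy as np
import pytest

from cdpreform import (
    PRINTED,
    DegradationSeries,
    activation_thermodynamics,
    compare_formulations,
    fit_arrhenius,
    fit_first_order,
    make_degradation,
    shelf_life,
)
from cdpreform.stats_core import DegenerateInputError


def _series(k, times, c0=100.0, temp=303.0, **kw):
    t = np.asarray(times, dtype=float)
    return DegradationSeries(condition=kw.pop("condition", "RH76"),
                             temperature=temp, times=tuple(t),
                             content=tuple(c0 * np.exp(-k * t)), **kw)


class TestFirstOrder:
    def test_exact_exponential(self):
        fit = fit_first_order(_series(1e-3, np.linspace(0, 5000, 6)))
        assert fit.kobs == pytest.approx(1e-3, rel=1e-12)
        assert fit.delta_k == pytest.approx(0.0, abs=1e-12)
        assert fit.degrading

    def test_constant_content_non_degrading(self):
        s = DegradationSeries(condition="RH76", temperature=303.0,
                              times=(0.0, 100.0, 200.0), content=(100.0,) * 3)
        with pytest.warns(UserWarning, match="no degradation"):
            fit = fit_first_order(s)
        assert fit.kobs == pytest.approx(0.0, abs=1e-15)
        assert not fit.degrading

    def test_nonpositive_content_names_row(self):
        with pytest.raises(ValueError, match="row 2"):
            DegradationSeries(condition="RH76", temperature=303.0,
                              times=(0.0, 1.0, 2.0), content=(100.0, 50.0, 0.0))

    def test_kobs_invariant_under_content_rescaling(self):
        t = np.linspace(0, 1e5, 8)
        a = fit_first_order(_series(3e-6, t, c0=100.0))
        b = fit_first_order(_series(3e-6, t, c0=7.3))
        assert a.kobs == pytest.approx(b.kobs, rel=1e-12)
        assert a.lnc0 != b.lnc0

    def test_delta_k_coverage_with_noise(self):
        """Δk half-width covers the true k in ~95% of noisy replicates."""
        true_k = 3.94e-6
        t = np.linspace(0, 3.5e5, 12)
        hits = 0
        n_rep = 200
        master = np.random.default_rng(7)
        for _ in range(n_rep):
            c = 100.0 * np.exp(-true_k * t) * (1 + 0.02 * master.standard_normal(12))
            s = DegradationSeries(condition="RH76", temperature=303.0,
                                  times=tuple(t), content=tuple(c))
            fit = fit_first_order(s, alpha=0.05)
            hits += abs(fit.kobs - true_k) <= fit.delta_k
        assert hits / n_rep >= 0.90  # nominal 95%, log-scale noise is approximate


class TestArrhenius:
    def test_two_temperatures_rejected(self):
        with pytest.raises(DegenerateInputError, match="3 distinct temperatures"):
            fit_arrhenius([(303.0, 1e-6), (313.0, 2e-6)])

    def test_closed_loop_noise_free(self, noise_free):
        ea, lnA = 1.2e4, -7.65
        sim = make_degradation(ea=ea, lnA=lnA, cfg=noise_free)
        ks = [(s.temperature, fit_first_order(s).kobs) for s in sim.series]
        arr = fit_arrhenius(ks)
        assert arr.ea == pytest.approx(ea, rel=1e-9)
        assert arr.lnA == pytest.approx(lnA, rel=1e-9)

    def test_printed_rate_ladder_consistency(self):
        """An Arrhenius law pinned at k(303 K) = 3.94e-6 with Ea = 12.07 kJ/mol
        predicts k(333 K) ≈ 6.1e-6 s^-1, matching the published ladder."""
        ea = 12.07e3
        lnA = math.log(3.94e-6) + ea / (PRINTED.R * 303.0)
        k333 = math.exp(lnA - ea / (PRINTED.R * 333.0))
        assert k333 == pytest.approx(6.12e-6, rel=0.02)


class TestActivationThermo:
    def test_dh_identity_exact(self):
        arr = fit_arrhenius([(303.0, 3.94e-6), (313.0, 4.80e-6), (323.0, 5.38e-6)])
        for t_ref in (1.0, 150.0, 298.0, 350.0):
            th = activation_thermodynamics(arr, t_ref=t_ref)
            assert th.dH + PRINTED.R * t_ref == pytest.approx(arr.ea, rel=1e-14)

    def test_entropy_variants(self):
        arr = fit_arrhenius([(303.0, 3.94e-6), (313.0, 4.80e-6), (323.0, 5.38e-6)])
        th = activation_thermodynamics(arr, t_ref=298.0)
        # as-printed variant is lnA-independent
        assert th.dS_as_printed == pytest.approx(
            -PRINTED.R * math.log(PRINTED.kB * 298.0 / PRINTED.h), rel=1e-12)
        # standard variant differs by R*lnA
        assert th.dS_standard - th.dS_as_printed == pytest.approx(
            PRINTED.R * arr.lnA, rel=1e-12)

    def test_low_t_ref_limit(self):
        arr = fit_arrhenius([(303.0, 3.94e-6), (313.0, 4.80e-6), (323.0, 5.38e-6)])
        th = activation_thermodynamics(arr, t_ref=1e-9)
        assert th.dH == pytest.approx(arr.ea, rel=1e-9)


class TestCompareFormulations:
    def test_identical_series_t0_zero(self):
        t = np.linspace(0, 1e5, 8)
        rng = np.random.default_rng(3)
        c = 100.0 * np.exp(-3e-6 * t) * (1 + 0.01 * rng.standard_normal(8))
        s = DegradationSeries(condition="RH76", temperature=303.0,
                              times=tuple(t), content=tuple(c), formulation="a")
        res = compare_formulations([s], [s])
        assert res[("RH76", 303.0)].t0 == 0.0

    def test_noise_free_rate_gap_exact_separation(self):
        t = np.linspace(0, 1e5, 8)
        a = _series(2e-6, t, formulation="a")
        b = _series(4e-6, t, formulation="b")
        res = compare_formulations([a], [b])[("RH76", 303.0)]
        assert res.exact_separation and res.significant

    def test_unmatched_condition_skipped_with_warning(self):
        t = np.linspace(0, 1e5, 8)
        a = _series(2e-6, t, temp=303.0)
        b = _series(2e-6, t, temp=313.0)
        with pytest.warns(UserWarning, match="no matching series"):
            res = compare_formulations([a], [b])
        assert res == {}


class TestShelfLife:
    def test_t90(self):
        fit = fit_first_order(_series(1e-6, np.linspace(0, 2e5, 6)))
        assert shelf_life(fit, 0.9) == pytest.approx(-math.log(0.9) / 1e-6, rel=1e-9)

    def test_boundary_fractions(self):
        fit = fit_first_order(_series(1.0, np.linspace(0, 5, 6)))
        assert shelf_life(fit, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert shelf_life(fit, math.exp(-1)) == pytest.approx(1.0, rel=1e-9)

    def test_undefined_for_non_degrading(self):
        s = DegradationSeries(condition="RH76", temperature=303.0,
                              times=(0.0, 1.0, 2.0), content=(100.0,) * 3)
        with pytest.warns(UserWarning):
            fit = fit_first_order(s)
        with pytest.raises(ValueError, match="kobs"):
            shelf_life(fit, 0.9)
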