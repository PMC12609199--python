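"""Bateman exposure model, Hill-effect aggregation, window coverage, dose
finding, and bioavailability scenarios."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import brentq

from masldscreen.pbpk import (
    PKParameters, WindowSpec, bateman_concentration,
    bioavailability_scenario, combine_effects, derive_pk_parameters,
    find_min_dose, hill_effect, simulate_combination, simulate_exposure,
    window_coverage,
)

GENISTEIN = PKParameters(ka=0.8, cl=0.1, vd=0.64, f=1.0, mw=270.24,
                         body_mass=70.0, dose_mg=100.0)


class TestParameters:
    @pytest.mark.parametrize("logp,vd", [(2.0, 0.64), (1.0, 0.62), (0.0, 0.60)])
    def test_vd_from_logp(self, logp, vd):
        p = derive_pk_parameters(mw=300.0, logp=logp, tpsa=90.0)
        assert p.vd == pytest.approx(vd)
        assert p.ka == 0.8 and p.cl == 0.1

    def test_override_row_takes_precedence(self):
        p = derive_pk_parameters(mw=300.0, logp=2.0, tpsa=90.0,
                                 overrides={"ka": 1.5, "f": 0.3})
        assert p.ka == 1.5 and p.f == 0.3
        assert p.cl == 0.1  # untouched default

    def test_missing_mw_errors(self):
        with pytest.raises(ValueError, match="MW"):
            derive_pk_parameters(mw=None, logp=1.0)

    def test_ka_equal_k_perturbed(self):
        with pytest.warns(UserWarning, match="epsilon"):
            p = PKParameters(ka=0.25, cl=0.1, vd=0.4, f=1.0, mw=300.0)
        assert p.ka != p.k


class TestBateman:
    def test_zero_at_time_zero(self):
        assert bateman_concentration(GENISTEIN, 0.0) == 0.0

    def test_genistein_reference_point(self):
        # independent closed-form evaluation: k = 0.15625 1/h
        assert GENISTEIN.k == pytest.approx(0.15625)
        assert GENISTEIN.tmax == pytest.approx(2.537, abs=0.005)
        assert GENISTEIN.cmax == pytest.approx(5.557, abs=0.005)

    def test_auc_identity_within_tenth_percent(self):
        # trapezoidal AUC out to 12 elimination half-lives vs F*D/(Cl*m)
        t_end = 12 * np.log(2) / GENISTEIN.k
        prof = simulate_exposure(GENISTEIN, t_end=t_end, dt=0.01)
        assert prof.auc_trapezoid() == pytest.approx(GENISTEIN.auc_inf,
                                                     rel=1e-3)

    def test_concentration_nonnegative_and_unimodal(self):
        prof = simulate_exposure(GENISTEIN)
        assert np.all(prof.c >= 0)
        assert prof.tmax == pytest.approx(GENISTEIN.tmax, abs=0.02 + 1e-9)
        peak = int(np.argmax(prof.c))
        assert np.all(np.diff(prof.c[:peak + 1]) >= -1e-12)
        assert np.all(np.diff(prof.c[peak:]) <= 1e-12)

    def test_dose_linearity(self):
        double = replace(GENISTEIN, dose_mg=200.0)
        assert double.cmax == pytest.approx(2 * GENISTEIN.cmax)

    def test_large_ka_approaches_bolus(self):
        fast = replace(GENISTEIN, ka=500.0)
        t = np.linspace(0.5, 12, 24)
        bolus = fast.f * fast.molar_dose_umol / fast.vd_total * \
            np.exp(-fast.k * t)
        np.testing.assert_allclose(bateman_concentration(fast, t), bolus,
                                   rtol=2e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bateman_concentration(GENISTEIN, -1.0)


class TestHillAndCombination:
    @pytest.mark.parametrize("c,ic50,expected", [
        (1.0, 1.0, 0.5), (0.0, 1.0, 0.0), (3.0, 1.0, 0.75),
    ])
    def test_hill_points(self, c, ic50, expected):
        assert hill_effect(c, ic50) == expected

    def test_combine_rules(self):
        assert combine_effects([0.5, 0.5], "hsa") == 0.5
        assert combine_effects([0.5, 0.5], "bliss") == 0.75
        assert combine_effects([0.4], "hsa") == combine_effects([0.4], "bliss") == 0.4
        assert combine_effects([], "bliss") == 0.0

    def test_bliss_dominates_hsa(self, rng):
        for _ in range(50):
            E = rng.random(rng.integers(1, 5))
            assert combine_effects(E, "bliss") >= \
                combine_effects(E, "hsa") - 1e-12


def _window(aggregation="bliss", t1=6.0, targets=("LIPG",)):
    return WindowSpec(name="postprandial", t0=0.0, t1=t1,
                      target_weights={t: 1.0 for t in targets},
                      ic50={t: 1.0 for t in targets},
                      aggregation=aggregation)


class TestWindowCoverage:
    def test_constant_high_exposure_full_coverage(self):
        prof = simulate_exposure(GENISTEIN)
        prof.c = np.full_like(prof.c, 2.0)   # E = 2/3 >= 0.5 throughout
        assert window_coverage([prof], _window()).aggregated == 100.0

    def test_zero_exposure_zero_coverage(self):
        prof = simulate_exposure(GENISTEIN)
        prof.c = np.zeros_like(prof.c)
        assert window_coverage([prof], _window()).aggregated == 0.0

    def test_crossings_match_analytic_roots(self):
        # single compound: E >= 0.5 is exactly C >= IC50; compare measured
        # coverage to the analytic Bateman root interval
        params = replace(GENISTEIN, f=0.135, dose_mg=160.0)
        dt = 0.02
        prof = simulate_exposure(params, t_end=24.0, dt=dt)
        cov = window_coverage([prof], _window()).aggregated

        func = lambda t: bateman_concentration(params, t) - 1.0
        t_lo = brentq(func, 1e-6, params.tmax)
        t_hi = brentq(func, params.tmax, 24.0)
        expected = 100.0 * (min(t_hi, 6.0) - t_lo) / 6.0
        measured_step = 100.0 * dt / 6.0
        assert abs(cov - expected) <= 2 * measured_step

    def test_mismatched_grids_rejected(self):
        a = simulate_exposure(GENISTEIN, t_end=24)
        b = simulate_exposure(GENISTEIN, t_end=12)
        with pytest.raises(ValueError, match="time grid"):
            window_coverage([a, b], _window())


class TestDoseFinding:
    def test_zero_target_returns_smallest_grid_dose(self):
        res = find_min_dose(GENISTEIN, _window(), coverage_target=0.0,
                            dose_grid=[50, 100, 200])
        assert res["achievable"] and res["msd_mg"] == 50

    def test_monotone_in_dose(self):
        params = replace(GENISTEIN, f=0.135)
        covs = []
        for dose in (50, 100, 160, 300):
            prof = simulate_exposure(replace(params, dose_mg=dose))
            covs.append(window_coverage([prof], _window()).aggregated)
        assert covs == sorted(covs)

    def test_bisection_agrees_with_dense_grid(self):
        # five toy parameterizations, dense-grid oracle at 1 mg resolution
        toys = [
            replace(GENISTEIN, f=0.135),
            replace(GENISTEIN, f=0.3, cl=0.2),
            PKParameters(ka=1.2, cl=0.15, vd=0.7, f=0.5, mw=350.0),
            PKParameters(ka=0.4, cl=0.05, vd=0.62, f=0.2, mw=450.0),
            PKParameters(ka=2.0, cl=0.3, vd=0.8, f=0.8, mw=280.0),
        ]
        w = _window()
        for params in toys:
            res = find_min_dose(params, w, coverage_target=50.0,
                                dose_grid=range(25, 1001, 100), refine_mg=1.0)
            dense = None
            for dose in range(25, 1001, 1):
                prof = simulate_exposure(replace(params, dose_mg=float(dose)))
                if window_coverage([prof], w).aggregated >= 50.0:
                    dense = dose
                    break
            if dense is None:
                assert not res["achievable"]
            else:
                assert res["achievable"]
                assert abs(res["msd_mg"] - dense) <= 1.0

    def test_unreachable_target_reported(self):
        params = replace(GENISTEIN, f=0.01)
        res = find_min_dose(params, _window(), coverage_target=90.0,
                            dose_grid=[10, 20], regulatory_cap_mg=50)
        assert not res["achievable"]
        assert res["msd_mg"] is None
        assert 0 <= res["best_coverage"] < 90


class TestCombination:
    def test_zero_dose_component_equals_monotherapy(self):
        w = _window()
        mono, _ = simulate_combination([(GENISTEIN, "genistein")], w)
        tiny = replace(GENISTEIN, dose_mg=1e-9, mw=610.52)
        combo, _ = simulate_combination(
            [(GENISTEIN, "genistein"), (tiny, "rutin")], w)
        assert combo.aggregated == pytest.approx(mono.aggregated, abs=1e-6)

    def test_adding_component_never_decreases_bliss_coverage(self):
        w = _window("bliss")
        rutin = PKParameters(ka=0.8, cl=0.1, vd=0.632, f=1.0, mw=610.52,
                             dose_mg=200.0)
        base, _ = simulate_combination([(GENISTEIN, "genistein")], w)
        more, _ = simulate_combination(
            [(GENISTEIN, "genistein"), (rutin, "rutin")], w)
        assert more.aggregated >= base.aggregated - 1e-12

    def test_two_component_effect_series_hand_check(self):
        w = _window("bliss")
        a = replace(GENISTEIN, f=0.135)
        b = PKParameters(ka=0.8, cl=0.1, vd=0.632, f=0.5, mw=610.52,
                         dose_mg=200.0)
        cov, profiles = simulate_combination([(a, "a"), (b, "b")], w)
        for t in (0.5, 1.0, 2.0, 4.0, 6.0):
            ea = hill_effect(bateman_concentration(a, t), 1.0)
            eb = hill_effect(bateman_concentration(b, t), 1.0)
            expected = 1 - (1 - ea) * (1 - eb)
            i = int(round(t / 0.02))
            got = 1 - (1 - hill_effect(profiles[0].c[i], 1.0)) * \
                (1 - hill_effect(profiles[1].c[i], 1.0))
            assert got == pytest.approx(expected, rel=1e-9)


class TestBioavailabilityScenario:
    def test_identity_factor(self):
        assert bioavailability_scenario(GENISTEIN, 1.0) == GENISTEIN

    def test_factor_scales_cmax_linearly(self):
        base = replace(GENISTEIN, f=0.1)
        boosted = bioavailability_scenario(base, 2.0)
        assert boosted.cmax == pytest.approx(2 * base.cmax)

    def test_phytosome_benchmark_capped(self):
        # the ~5.2x quercetin-style enhancement caps F at 1
        base = replace(GENISTEIN, f=0.3)
        with pytest.warns(UserWarning, match="capping"):
            boosted = bioavailability_scenario(base, 5.2)
        assert boosted.f == 1.0
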