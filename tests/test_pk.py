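"""One-compartment PK model, fitting, NCA and summary statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from dotinurad_pkpd import (
    DoseRegimen,
    PKParams,
    PlasmaProfile,
    accumulation_ratio,
    auc_trapezoid,
    concentration,
    concentration_auc,
    dose_proportionality,
    fit_pk,
    geometric_mean_ratio,
    nca,
    theoretical_accumulation_ratio,
)
from dotinurad_pkpd.errors import (
    DegenerateParameterError,
    InsufficientDesignError,
    TerminalPhaseError,
    UninformativeDataError,
)
from dotinurad_pkpd.pk import tmax_single_dose

from conftest import SAD_TIMES, make_profile


class TestConcentration:
    def test_zero_at_and_before_dose_time(self, ref_pk, single_5mg):
        assert concentration(ref_pk, single_5mg, 0.0) == 0.0
        reg = DoseRegimen(5.0, start_time_h=2.0)
        assert concentration(ref_pk, reg, 1.0) == 0.0

    def test_peak_value_matches_ode_oracle(self, ref_pk, single_5mg):
        """Analytic curve agrees with numeric integration of the two-state
        absorption/elimination ODE; peak ~363.7 ng/mL at ~3.29 h."""
        dose_ng = single_5mg.dose_ng

        def rhs(t, y):
            gut, cp = y
            return [-ref_pk.ka * gut,
                    ref_pk.ka * gut / ref_pk.v_f - ref_pk.ke * cp]

        t_eval = np.array([0.5, 1.0, 3.288390287020193, 8.0, 24.0, 48.0])
        sol = solve_ivp(rhs, (0.0, 48.0), [dose_ng, 0.0], t_eval=t_eval,
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            concentration(ref_pk, single_5mg, t_eval), sol.y[1], rtol=1e-7
        )
        tmax = tmax_single_dose(ref_pk)
        assert tmax == pytest.approx(3.2884, abs=1e-3)
        assert concentration(ref_pk, single_5mg, tmax) == pytest.approx(363.7, abs=0.1)

    def test_superposition_is_exact(self, ref_pk):
        """n-dose curve equals the sum of n time-shifted single-dose curves
        at machine precision."""
        multi = DoseRegimen(2.0, interval_h=24.0, n_doses=5)
        t = np.linspace(0.0, 140.0, 301)
        summed = sum(
            np.atleast_1d(concentration(ref_pk, DoseRegimen(2.0, start_time_h=td), t))
            for td in multi.dose_times()
        )
        np.testing.assert_allclose(concentration(ref_pk, multi, t), summed,
                                   rtol=1e-14, atol=1e-14)

    def test_dose_linearity_pointwise(self, ref_pk):
        t = np.linspace(0.0, 48.0, 100)
        c1 = concentration(ref_pk, DoseRegimen(5.0), t)
        c2 = concentration(ref_pk, DoseRegimen(10.0), t)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-14)

    def test_steady_state_daily_auc_identity(self, ref_pk):
        """At steady state the daily AUC equals dose/(Ke*V/F) ~ 5.94e3
        ng*h/mL; the exact interval integral and a dense trapezoid agree."""
        reg = DoseRegimen(5.0, interval_h=24.0, n_doses=60)
        expected = reg.dose_ng / (ref_pk.ke * ref_pk.v_f)
        assert expected == pytest.approx(5.94e3, rel=1e-3)
        t0, t1 = 24.0 * 58, 24.0 * 59
        assert concentration_auc(ref_pk, reg, t0, t1) == pytest.approx(
            expected, rel=1e-6
        )
        t = np.linspace(t0, t1, 20001)
        dense = np.trapezoid(concentration(ref_pk, reg, t), t)
        assert dense == pytest.approx(expected, rel=1e-4)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(DegenerateParameterError):
            PKParams(v_f=1000.0, ka=0.1, ke=0.1)


class TestFitPK:
    def test_noise_free_recovery(self, ref_pk, single_5mg):
        fit = fit_pk(make_profile(ref_pk, single_5mg))
        assert fit.params.v_f == pytest.approx(ref_pk.v_f, rel=1e-6)
        assert fit.params.ka == pytest.approx(ref_pk.ka, rel=1e-6)
        assert fit.params.ke == pytest.approx(ref_pk.ke, rel=1e-6)
        assert fit.rss < 1e-12

    def test_dose_invariance(self, ref_pk):
        """Scaling dose and concentrations together leaves the linear-model
        parameters unchanged."""
        p1 = make_profile(ref_pk, DoseRegimen(5.0))
        p2 = PlasmaProfile("s", p1.times, 2.0 * p1.concentrations,
                           DoseRegimen(10.0))
        f1, f2 = fit_pk(p1), fit_pk(p2)
        assert f2.params.v_f == pytest.approx(f1.params.v_f, rel=1e-8)
        assert f2.params.ka == pytest.approx(f1.params.ka, rel=1e-8)
        assert f2.params.ke == pytest.approx(f1.params.ke, rel=1e-8)

    def test_monte_carlo_median_unbiased(self, ref_pk, single_5mg):
        """Median of replicate fits under 10% lognormal residual stays
        within a few percent of the generating values."""
        rng = np.random.default_rng(7)
        est = []
        for _ in range(200):
            prof = make_profile(ref_pk, single_5mg, noise_cv=0.10, rng=rng)
            p = fit_pk(prof).params
            est.append([p.v_f, p.ka, p.ke])
        med = np.median(est, axis=0)
        np.testing.assert_allclose(
            med, [ref_pk.v_f, ref_pk.ka, ref_pk.ke], rtol=0.05
        )

    def test_all_zero_concentrations_signal(self, single_5mg):
        prof = PlasmaProfile("s", SAD_TIMES, np.zeros_like(SAD_TIMES),
                             single_5mg)
        with pytest.raises(UninformativeDataError):
            fit_pk(prof)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        ke=st.floats(0.03, 0.3),
        ratio=st.floats(2.0, 50.0),
        v_f=st.floats(3000.0, 30000.0),
    )
    def test_recovery_across_flipflop_range(self, ke, ratio, v_f):
        """Noise-free recovery holds throughout Ka/Ke in [2, 50]."""
        true = PKParams(v_f=v_f, ka=ke * ratio, ke=ke)
        reg = DoseRegimen(5.0)
        # dense-enough schedule to keep >= 2 ascending samples even for
        # very fast absorption
        t = np.unique(np.concatenate([[0.1, 0.15], SAD_TIMES, [72.0, 96.0]]))
        fit = fit_pk(make_profile(true, reg, times=t))
        assert fit.params.ka == pytest.approx(true.ka, rel=1e-3)
        assert fit.params.ke == pytest.approx(true.ke, rel=1e-3)
        assert fit.params.v_f == pytest.approx(true.v_f, rel=1e-3)


class TestNCA:
    def test_triangle_auc(self):
        assert auc_trapezoid([0.0, 1.0, 2.0], [0.0, 100.0, 0.0]) == 100.0

    def test_auc_inf_converges_to_closed_form(self, ref_pk, single_5mg):
        """Dense-grid NCA AUC0-inf lands within 0.5% of dose/(Ke*V/F)."""
        t = np.arange(0.0, 120.0 + 1e-9, 0.01)
        prof = PlasmaProfile("s", t, np.atleast_1d(
            concentration(ref_pk, single_5mg, t)), single_5mg)
        res = nca(prof)
        closed = single_5mg.dose_ng / (ref_pk.ke * ref_pk.v_f)
        assert res.auc_0_inf == pytest.approx(closed, rel=5e-3)
        assert res.cl_f == pytest.approx(ref_pk.cl_f, rel=5e-3)
        assert res.tmax == pytest.approx(tmax_single_dose(ref_pk), abs=0.01)

    def test_t_half_exact_on_monoexponential_tail(self):
        """A purely log-linear terminal phase returns t1/2 = ln2/Ke."""
        ke = 0.0795
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0])
        c = np.where(t < 2.0, 50.0 * t, 100.0 * np.exp(-ke * (t - 2.0)))
        prof = PlasmaProfile("s", t, c, DoseRegimen(5.0))
        res = nca(prof)
        assert res.t_half == pytest.approx(math.log(2.0) / ke, rel=1e-9)
        assert res.lambda_z == pytest.approx(ke, rel=1e-9)

    def test_cmax_tie_resolves_to_earliest_time(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 6.0, 12.0, 24.0, 36.0])
        c = np.array([0.0, 50.0, 100.0, 100.0, 60.0, 30.0, 10.0, 3.0])
        res = nca(PlasmaProfile("s", t, c, DoseRegimen(5.0)))
        assert res.tmax == 2.0 and res.cmax == 100.0

    def test_missing_24h_sample_interpolated_and_flagged(self, ref_pk,
                                                         single_5mg):
        t = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 30.0, 48.0])
        res = nca(make_profile(ref_pk, single_5mg, times=t))
        assert res.interpolated_24h
        # interpolated AUC0-24 close to the exact integral (trapezoid bias only)
        exact = concentration_auc(ref_pk, single_5mg, 0.0, 24.0)
        assert res.auc_0_24 == pytest.approx(exact, rel=0.05)

    def test_non_estimable_terminal_phase_signals(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 24.0])
        c = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])  # still ascending
        with pytest.raises(TerminalPhaseError):
            nca(PlasmaProfile("s", t, c, DoseRegimen(5.0)))


class TestSummaryStats:
    def test_accumulation_ratio_values(self, ref_pk):
        assert accumulation_ratio(1000.0, 1000.0).r_auc == 1.0
        # observed multiple-dose daily AUCs give the printed ratio
        assert accumulation_ratio(2195.0, 2680.0).r_auc == pytest.approx(1.22,
                                                                         abs=0.005)
        with pytest.raises(ValueError):
            accumulation_ratio(0.0, 1000.0)

    def test_accumulation_matches_superposition_identity(self, ref_pk,
                                                         single_5mg):
        """Steady-state daily AUC equals the single-dose AUC0-inf
        (superposition), so the model accumulation ratio is
        AUC0-inf/AUC0-24 ~ 1.20, inside the observed 1.18-1.22 range; the
        elimination-only shortcut 1/(1-exp(-Ke*tau)) ~ 1.17 bounds it from
        below."""
        reg = DoseRegimen(5.0, interval_h=24.0, n_doses=60)
        auc1 = concentration_auc(ref_pk, reg, 0.0, 24.0)
        auc_ss = concentration_auc(ref_pk, reg, 24.0 * 58, 24.0 * 59)
        auc_inf_single = single_5mg.dose_ng / (ref_pk.ke * ref_pk.v_f)
        assert auc_ss == pytest.approx(auc_inf_single, rel=1e-6)
        model_ratio = auc_ss / auc1
        assert model_ratio == pytest.approx(1.198, abs=0.002)
        assert 1.18 <= model_ratio <= 1.22
        shortcut = theoretical_accumulation_ratio(ref_pk.ke, 24.0)
        assert shortcut == pytest.approx(1.174, abs=0.001)
        assert shortcut <= model_ratio

    def test_power_model_slopes(self, ref_pk):
        doses = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
        exact = dose_proportionality([(d, 30.0 * d) for d in doses])
        assert exact.slope == pytest.approx(1.0, abs=1e-12)
        quad = dose_proportionality([(d, 2.0 * d**2) for d in doses])
        assert quad.slope == pytest.approx(2.0, abs=1e-12)
        # noise-free Cmax from the linear PK model is exactly proportional
        cmaxes = [
            (d, concentration(ref_pk, DoseRegimen(d), tmax_single_dose(ref_pk)))
            for d in doses
        ]
        fit = dose_proportionality(cmaxes)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_ci90[0] <= 1.0 <= fit.slope_ci90[1]
        with pytest.raises(InsufficientDesignError):
            dose_proportionality([(1.0, 10.0), (2.0, 20.0)])

    def test_geometric_mean_ratio(self):
        same = geometric_mean_ratio([(100.0, 100.0)] * 4)
        assert same.gmr == 1.0
        assert same.ci90 == pytest.approx((1.0, 1.0))
        down = geometric_mean_ratio([(80.0, 100.0)] * 4)
        assert down.gmr == pytest.approx(0.8, rel=1e-12)

    def test_gmr_ci_matches_paired_t_formula(self):
        """CI from the implementation equals the textbook paired-t interval
        computed by hand on the log scale."""
        from scipy import stats

        test = np.array([90.0, 110.0, 85.0, 105.0, 95.0, 100.0])
        ref = np.array([100.0, 100.0, 100.0, 100.0, 100.0, 100.0])
        d = np.log(test) - np.log(ref)
        se = d.std(ddof=1) / np.sqrt(6)
        tcrit = stats.t.ppf(0.95, 5)
        res = geometric_mean_ratio(list(zip(test, ref)))
        assert res.gmr == pytest.approx(math.exp(d.mean()), rel=1e-12)
        assert res.ci90[0] == pytest.approx(math.exp(d.mean() - tcrit * se), rel=1e-12)
        assert res.ci90[1] == pytest.approx(math.exp(d.mean() + tcrit * se), rel=1e-12)
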