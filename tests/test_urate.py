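"""Urate physiology, the PD estimation cascade and the Emax fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dotinurad_pkpd import (
    DeltaSummary,
    DoseRegimen,
    EmaxParams,
    PlasmaProfile,
    SimulationConfig,
    UratePhysiology,
    UrineInterval,
    clearance_from_excretion,
    concentration,
    derive_baseline,
    effect_fraction,
    estimate_freabs,
    estimate_vd_ua,
    fit_emax,
    implied_gfr,
    interval_means,
    renal_clearance,
    simulate_sua,
)
from dotinurad_pkpd.errors import (
    InconsistentDeltaError,
    MissingIntervalError,
    NetSecretionError,
    NonIdentifiableError,
)


class TestClearanceAndBaseline:
    def test_clearance_from_excretion_units(self):
        """575 mg over a flat 5.71 mg/dL day (AUEC 137.04 mg*h/dL) is
        ~6.99 mL/min, matching the cohort mean of ~7.1."""
        assert clearance_from_excretion(575.0, 5.71 * 24.0) == pytest.approx(
            6.993, abs=0.001
        )
        assert clearance_from_excretion(0.0, 100.0) == 0.0
        assert clearance_from_excretion(1150.0, 2 * 137.04) == pytest.approx(
            clearance_from_excretion(575.0, 137.04)
        )
        with pytest.raises(ValueError):
            clearance_from_excretion(575.0, 0.0)

    def test_derive_baseline_split(self):
        rates = derive_baseline(575.0, 7.10)
        assert rates.xf_ua_mg_day == 287.5
        assert rates.synthesis_mg_day == 862.5
        assert rates.clgut_ua_ml_min == 3.55
        zero = derive_baseline(0.0, 0.0)
        assert (zero.xf_ua_mg_day, zero.synthesis_mg_day,
                zero.clgut_ua_ml_min) == (0.0, 0.0, 0.0)

    def test_baseline_closure_synthesis_equals_total_excretion(self):
        """Synthesis = Xu + Xf exactly (steady-state restatement)."""
        rates = derive_baseline(575.0, 7.10)
        assert rates.synthesis_mg_day == 575.0 + rates.xf_ua_mg_day

    def test_physiology_invariants_enforced(self):
        with pytest.raises(ValueError, match="2:1"):
            UratePhysiology(
                vd_ua=16000.0, f_reabs=0.943, gfr=124.56, clgut_ua=5.0,
                synthesis_rate=36.5, baseline_sua=5.71, baseline_clr_ua=7.10,
            )
        with pytest.raises(ValueError, match="steady state"):
            UratePhysiology(
                vd_ua=16000.0, f_reabs=0.943, gfr=124.5614, clgut_ua=3.55,
                synthesis_rate=99.0, baseline_sua=5.71, baseline_clr_ua=7.10,
            )


class TestVolumeEstimator:
    def test_simple_arithmetic(self):
        assert estimate_vd_ua(
            DeltaSummary(d_xu_ua=320.0, d_xf_ua=0.0, d_sua=2.0)
        ) == 16000.0

    def test_error_signals(self):
        with pytest.raises(ValueError):
            estimate_vd_ua(DeltaSummary(d_xu_ua=320.0, d_xf_ua=0.0, d_sua=0.0))
        with pytest.raises(InconsistentDeltaError):
            estimate_vd_ua(DeltaSummary(d_xu_ua=10.0, d_xf_ua=-20.0, d_sua=1.0))

    def test_mass_balance_round_trip(self, ref_phys, ref_emax, ref_pk):
        """Deltas produced by the conservative simulator return the
        generating volume to machine precision."""
        from dotinurad_pkpd.simulate import single_dose_deltas

        course = simulate_sua(ref_phys, ref_emax, ref_pk, DoseRegimen(5.0),
                              SimulationConfig())
        vd = estimate_vd_ua(single_dose_deltas(course))
        assert vd == pytest.approx(ref_phys.vd_ua, rel=1e-9)


class TestReabsorption:
    def test_freabs_values(self):
        assert estimate_freabs(7.10, 124.6) == pytest.approx(0.943, abs=5e-4)
        assert estimate_freabs(0.0, 100.0) == 1.0
        assert estimate_freabs(100.0, 100.0) == 0.0
        with pytest.raises(NetSecretionError):
            estimate_freabs(120.0, 100.0)

    def test_implied_gfr_values(self):
        assert implied_gfr(7.10, 0.943) == pytest.approx(124.56, abs=0.01)
        assert implied_gfr(42.0, 0.0) == 42.0
        assert implied_gfr(0.0, 0.5) == 0.0
        with pytest.raises(ValueError):
            implied_gfr(7.10, 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(clr=st.floats(0.1, 50.0), f=st.floats(0.0, 0.99))
    def test_freabs_implied_gfr_round_trip(self, clr, f):
        assert estimate_freabs(clr, implied_gfr(clr, f)) == pytest.approx(
            f, abs=1e-12
        )


class TestEffectModel:
    def test_effect_fraction_anchors(self, ref_emax):
        assert effect_fraction(ref_emax, 0.0) == 0.0
        assert effect_fraction(ref_emax, 196.0) == pytest.approx(0.255)
        assert effect_fraction(ref_emax, 1960.0) == pytest.approx(
            0.51 * 10 / 11
        )

    def test_renal_clearance_anchors(self, ref_phys, ref_emax):
        assert renal_clearance(ref_phys, ref_emax, 0.0) == pytest.approx(7.10)
        # saturating concentration approaches GFR*(1 - f*(1 - Emax)) ~ 67
        assert renal_clearance(ref_phys, ref_emax, 1e12) == pytest.approx(
            67.0, abs=0.05
        )

    def test_renal_clearance_without_reabsorption_is_gfr(self, ref_emax):
        phys = UratePhysiology.from_baseline(5.71, 50.0, vd_ua_ml=16000.0,
                                             f_reabs=0.0)
        cps = np.array([0.0, 10.0, 1000.0])
        np.testing.assert_allclose(renal_clearance(phys, ref_emax, cps),
                                   phys.gfr)

    def test_renal_clearance_monotone_concave_bounded(self, ref_phys,
                                                      ref_emax):
        cp = np.linspace(0.0, 5000.0, 400)
        clr = renal_clearance(ref_phys, ref_emax, cp)
        assert np.all(np.diff(clr) > 0)
        assert np.all(np.diff(clr, 2) < 1e-12)  # concave
        lo = ref_phys.gfr * (1 - ref_phys.f_reabs)
        hi = ref_phys.gfr * (1 - ref_phys.f_reabs * (1 - ref_emax.emax))
        assert np.all(clr >= lo - 1e-12) and np.all(clr <= hi + 1e-12)


def _simulated_subject(phys, emax, pk, dose=5.0):
    """Noise-free observed tables for one subject from the simulator."""
    reg = DoseRegimen(dose)
    cfg = SimulationConfig(
        dt=0.05, t_start=-24.0, horizon=48.0,
        record_intervals=((-24.0, 0.0), (0.0, 6.0), (6.0, 12.0),
                          (12.0, 24.0), (24.0, 36.0), (36.0, 48.0)),
    )
    course = simulate_sua(phys, emax, pk, reg, cfg)
    t = np.arange(0.0, 48.0 + 1e-9, 0.25)
    profile = PlasmaProfile(
        "s", t, np.atleast_1d(concentration(pk, reg, t)), reg
    )
    urine = [
        UrineInterval(r.window_start_h, r.window_end_h, 1.0, r.xu_mg)
        for r in course.intervals.itertuples()
    ]
    mask = course.times >= 0
    return profile, urine, course.times[mask], course.sua[mask], course


class TestIntervalMeans:
    def test_constant_concentration_mean(self, ref_phys):
        t = np.arange(0.0, 48.0 + 1e-9, 1.0)
        profile = PlasmaProfile("s", t, np.full_like(t, 42.0), DoseRegimen(5.0))
        sua = np.full_like(t, ref_phys.baseline_sua)
        # urine consistent with baseline clearance at constant SUA
        from dotinurad_pkpd import units

        xu_rate = (
            units.ml_per_min_to_dl_per_h(ref_phys.baseline_clr_ua)
            * ref_phys.baseline_sua
        )
        urine = [
            UrineInterval(a, b, 1.0, xu_rate * (b - a))
            for a, b in ((0, 6), (6, 12), (12, 24), (24, 48))
        ]
        pts = interval_means(profile, urine, t, sua,
                             gfr_ml_min=ref_phys.gfr,
                             f_reabs=ref_phys.f_reabs)
        assert all(p.cp_mean == pytest.approx(42.0) for p in pts)
        assert all(p.effect == pytest.approx(0.0, abs=1e-12) for p in pts)

    def test_selfconsistency_on_simulated_subject(self, ref_phys, ref_emax,
                                                  ref_pk):
        """Back-calculated window effects track the Emax model evaluated at
        the window-mean concentration (up to the window-aggregation bias)."""
        profile, urine, sua_t, sua_v, _ = _simulated_subject(
            ref_phys, ref_emax, ref_pk
        )
        pts = interval_means(profile, urine, sua_t, sua_v,
                             gfr_ml_min=ref_phys.gfr,
                             f_reabs=ref_phys.f_reabs)
        for p in pts:
            assert p.effect == pytest.approx(
                effect_fraction(ref_emax, p.cp_mean), abs=0.03
            )

    def test_placebo_effects_are_zero(self, ref_phys, ref_emax, ref_pk):
        profile, urine, sua_t, sua_v, _ = _simulated_subject(
            ref_phys, ref_emax, ref_pk, dose=0.0
        )
        pts = interval_means(profile, urine, sua_t, sua_v,
                             gfr_ml_min=ref_phys.gfr,
                             f_reabs=ref_phys.f_reabs)
        assert all(p.effect == pytest.approx(0.0, abs=1e-9) for p in pts)
        assert all(p.cp_mean == 0.0 for p in pts)

    def test_missing_urine_window_signals(self, ref_phys):
        t = np.arange(0.0, 48.0 + 1e-9, 1.0)
        profile = PlasmaProfile("s", t, np.full_like(t, 10.0), DoseRegimen(5.0))
        sua = np.full_like(t, 5.71)
        urine = [UrineInterval(0.0, 6.0, 1.0, 10.0)]  # nothing past 6 h
        with pytest.raises(MissingIntervalError):
            interval_means(profile, urine, t, sua, gfr_ml_min=ref_phys.gfr,
                           f_reabs=ref_phys.f_reabs)


class TestEmaxFit:
    def test_noise_free_recovery(self, ref_emax):
        cps = np.array([10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0])
        pts = list(zip(cps, effect_fraction(ref_emax, cps)))
        fit = fit_emax(pts)
        assert fit.params.emax == pytest.approx(0.51, rel=1e-6)
        assert fit.params.ec50 == pytest.approx(196.0, rel=1e-6)
        assert fit.rss < 1e-15

    def test_all_zero_effects_non_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fit_emax([(10.0, 0.0), (100.0, 0.0), (1000.0, 0.0)])

    def test_concentration_rescaling_moves_only_ec50(self, ref_emax):
        cps = np.array([10.0, 50.0, 200.0, 800.0])
        effects = effect_fraction(ref_emax, cps)
        fit = fit_emax(list(zip(cps * 3.0, effects)))
        assert fit.params.emax == pytest.approx(ref_emax.emax, rel=1e-6)
        assert fit.params.ec50 == pytest.approx(3.0 * ref_emax.ec50, rel=1e-6)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(emax=st.floats(0.1, 0.9), ec50=st.floats(50.0, 1000.0))
    def test_recovery_across_parameter_range(self, emax, ec50):
        true = EmaxParams(emax=emax, ec50=ec50)
        cps = np.array([10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])
        fit = fit_emax(list(zip(cps, effect_fraction(true, cps))))
        assert fit.params.emax == pytest.approx(emax, rel=1e-4)
        assert fit.params.ec50 == pytest.approx(ec50, rel=1e-4)
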