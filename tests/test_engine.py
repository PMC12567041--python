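"""PBPK engine: conservation, limits, first pass, interaction layer, EHC."""

import numpy as np
import pytest

from ascipk import (EngineOptions, PBPKSystem, first_pass, load_compound,
                    pk_metrics)
from ascipk.engine import induction_rate, inhibition_modifier


class TestSystemStructure:
    def test_zero_dose_stays_at_zero(self, asciminib, subject, calibration):
        system = PBPKSystem(asciminib, subject, calibration=calibration)
        res = system.simulate({"asciminib": []}, duration=24.0)
        assert np.all(res.plasma_conc() == 0.0)

    def test_mass_balance_within_tenth_percent(self, single_dose_40):
        assert single_dose_40.mass_balance_error() < 1e-3

    def test_unknown_dose_target_rejected(self, asciminib, subject, calibration):
        system = PBPKSystem(asciminib, subject, calibration=calibration)
        with pytest.raises(KeyError):
            system.simulate({"somethingelse": [(0.0, 10.0)]}, duration=12.0)

    def test_perpetrator_without_interactions_warns(self, asciminib, subject,
                                                    calibration):
        inert = load_compound("midazolam").model_copy(deep=True)
        inert.inhibition = []
        with pytest.warns(UserWarning, match="interaction"):
            PBPKSystem(asciminib, subject, perpetrators=[inert],
                       calibration=calibration)

    def test_simulation_is_deterministic(self, asciminib, subject, calibration):
        def run():
            system = PBPKSystem(asciminib, subject, calibration=calibration)
            return system.simulate({"asciminib": [(0.0, 20.0)]}, duration=24.0)
        a, b = run(), run()
        assert np.array_equal(a.y, b.y)


class TestBcrpEffluxKinetics:
    def test_flux_saturates_at_jmax(self, asciminib, subject, calibration):
        """Far above Km the canalicular flux is zero order at
        Jmax × activity scalar."""
        system = PBPKSystem(asciminib, subject, calibration=calibration)
        y = system.initial_state()
        y[system.i_ic] = system.v_ic * system.k_liver_u * 1000 * system.km_bcrp
        dy = system.rhs(0.0, y)
        assert dy[system.i_bile] == pytest.approx(system.jmax_total, rel=2e-3)

    def test_flux_linear_far_below_km(self, asciminib, subject, calibration):
        system = PBPKSystem(asciminib, subject, calibration=calibration)
        y1 = system.initial_state()
        y1[system.i_ic] = system.v_ic * system.k_liver_u * 1e-4 * system.km_bcrp
        y2 = y1.copy()
        y2[system.i_ic] *= 2.0
        f1 = system.rhs(0.0, y1)[system.i_bile]
        f2 = system.rhs(0.0, y2)[system.i_bile]
        assert f2 == pytest.approx(2 * f1, rel=1e-3)


class TestFirstPass:
    def test_baseline_components(self, asciminib, subject, calibration):
        b = first_pass(asciminib, subject, calibration=calibration)
        assert 0.82 <= b.fg <= 0.84
        assert 0.90 <= b.fh <= 0.94
        assert b.f == pytest.approx(0.73, abs=0.03)

    def test_unbound_gut_limit(self, asciminib, subject, calibration):
        free = asciminib.model_copy(deep=True)
        free.absorption.fu_gut = 1e-9
        b = first_pass(free, subject, calibration=calibration)
        assert b.fg == pytest.approx(1.0, abs=1e-6)

    def test_fg_decreases_with_gut_intrinsic_clearance(self, asciminib,
                                                       subject, calibration):
        base = first_pass(asciminib, subject, calibration=calibration)
        doubled = first_pass(asciminib, subject, gut_induction=2.0,
                             calibration=calibration)
        assert doubled.fg < base.fg

    def test_inhibition_raises_both_components(self, asciminib, subject,
                                               calibration):
        inhibited = first_pass(asciminib, subject, gut_inhibition=10.0,
                               liver_inhibition=10.0, calibration=calibration)
        base = first_pass(asciminib, subject, calibration=calibration)
        assert inhibited.fg > base.fg and inhibited.fh > base.fh


class TestInteractionPrimitives:
    def test_inhibition_identity_and_half(self):
        assert inhibition_modifier(10.0, [0.0], [1.0]) == 10.0
        assert inhibition_modifier(10.0, [1.0], [1.0]) == 5.0
        assert inhibition_modifier(12.0, [1.0, 2.0], [1.0, 1.0]) == 3.0

    def test_inhibition_requires_positive_ki(self):
        with pytest.raises(ValueError):
            inhibition_modifier(10.0, [1.0], [0.0])

    def test_induction_steady_state_fold(self):
        """At dE/dt = 0 the level equals 1 + (Indmax−1)·I/(IndC50+I)."""
        indc50, indmax, kdeg = 0.32, 15.94, 0.0193
        i = 0.64
        e_ss = 1.0 + (indmax - 1.0) * i / (indc50 + i)
        assert induction_rate(e_ss, i, indc50, indmax, kdeg) == pytest.approx(0.0)
        assert induction_rate(1.0, 0.0, indc50, indmax, kdeg) == 0.0

    def test_induction_washout_decays_at_kdeg(self):
        kdeg = 0.0193
        rate = induction_rate(5.0, 0.0, 0.32, 15.94, kdeg)
        assert rate == pytest.approx(-kdeg * 4.0)

    def test_disabled_interactions_leave_victim_unchanged(self, asciminib,
                                                          subject, calibration):
        """With every interaction mechanism off, dosing a perpetrator does
        not alter the victim profile."""
        opts = EngineOptions(inhibition_enabled=False, induction_enabled=False)
        clar = load_compound("clarithromycin")
        system = PBPKSystem(asciminib, subject, opts, perpetrators=[clar],
                            calibration=calibration)
        solo = system.simulate({"asciminib": [(0.0, 40.0)]}, duration=48.0)
        both = system.simulate({"asciminib": [(0.0, 40.0)],
                                "clarithromycin": [(0.0, 500.0)]},
                               duration=48.0)
        # identical dynamics; differences are solver step-control noise only
        assert np.allclose(solo.plasma_conc(), both.plasma_conc(),
                           rtol=1e-4, atol=1e-3)


class TestLinearityAndRecirculation:
    def test_dose_proportionality_without_bcrp(self, asciminib, subject,
                                               calibration):
        """With the transporter off and all Michaelis–Menten terms in their
        linear regime, AUC scales exactly with dose."""
        opts = EngineOptions(bcrp_enabled=False)
        metrics = []
        for dose in (1.0, 10.0):
            system = PBPKSystem(asciminib, subject, opts,
                                calibration=calibration)
            res = system.simulate({"asciminib": [(0.0, dose)]}, duration=120.0)
            metrics.append(pk_metrics(res.t, res.plasma_conc(), 0.0))
        assert metrics[1].auc_inf / metrics[0].auc_inf == pytest.approx(10.0,
                                                                        rel=5e-3)

    def test_ehc_off_is_identical_to_base_model(self, asciminib, subject,
                                                calibration, single_dose_40):
        system = PBPKSystem(asciminib, subject,
                            EngineOptions(ehc_fraction=0.0),
                            calibration=calibration)
        res = system.simulate({"asciminib": [(0.0, 40.0)]}, duration=120.0)
        assert np.array_equal(res.y, single_dose_40.y)

    def test_auc_nondecreasing_in_reabsorbed_fraction(self, asciminib, subject,
                                                      calibration,
                                                      single_dose_40):
        aucs = [pk_metrics(single_dose_40.t, single_dose_40.plasma_conc(),
                           0.0).auc_inf]
        for frac in (0.5, 1.0):
            system = PBPKSystem(asciminib, subject,
                                EngineOptions(ehc_fraction=frac),
                                calibration=calibration)
            res = system.simulate({"asciminib": [(0.0, 40.0)]}, duration=120.0)
            aucs.append(pk_metrics(res.t, res.plasma_conc(), 0.0).auc_inf)
        assert aucs[0] < aucs[1] < aucs[2]

    def test_invalid_ehc_fraction_rejected(self):
        with pytest.raises(ValueError):
            EngineOptions(ehc_fraction=1.5)


class TestSteadyStateBehaviour:
    def test_day15_auc_within_5pct_of_day28(self, asciminib, subject,
                                            calibration):
        system = PBPKSystem(asciminib, subject, calibration=calibration)
        times = [(i * 12.0, 20.0) for i in range(56)]
        res = system.simulate({"asciminib": times}, duration=672.0)
        conc = res.plasma_conc()

        def auc_tau(day):
            m = (res.t >= (day - 1) * 24 + 12) & (res.t <= day * 24)
            return np.trapezoid(conc[m], res.t[m])

        assert auc_tau(15) == pytest.approx(auc_tau(28), rel=0.05)

    def test_bcrp_fraction_decreases_with_dose(self, clf_by_dose):
        """Saturation of the biliary efflux: its CL/F contribution falls
        monotonically from ~31% at 20 mg BID toward ~5% at 200 mg BID."""
        fts = [1.0 - wo / w for (w, wo) in
               (clf_by_dose[d] for d in (20.0, 40.0, 80.0, 200.0))]
        assert all(a > b for a, b in zip(fts, fts[1:]))
        assert fts[0] == pytest.approx(0.311, abs=0.02)
        assert fts[-1] < 0.10
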