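"""Compound library: validation, config round trips, in-vitro conversions."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from ascipk.compounds import (available_compounds, ki_from_ic50, km_unbound,
                              load_compound, save_compound)


class TestAsciminibFixture:
    """The shipped asciminib parameterisation reproduces the published
    model-input table cell by cell."""

    def test_physchem_and_binding(self, asciminib):
        assert asciminib.phys_chem.molecular_weight == 449.85
        assert asciminib.phys_chem.logp == 3.9
        assert asciminib.phys_chem.compound_class == "monoprotic base"
        assert asciminib.phys_chem.pka == 4.0
        assert asciminib.binding.fu_plasma == 0.027
        assert asciminib.binding.fu_plasma_renal_impaired == 0.018
        assert asciminib.binding.blood_to_plasma == 0.80

    def test_absorption_block(self, asciminib):
        a = asciminib.absorption
        assert a.ka == 1.3 and a.ka_cv == 9.0
        assert a.tlag == 0.374
        assert a.fu_gut == 0.25 and a.q_gut == 5.3
        assert a.fa == 0.96  # effective absorbed fraction entering F = fa·Fg·Fh
        assert a.peff_human == 3.729

    def test_distribution_block(self, asciminib):
        assert asciminib.distribution.kp_scalar == 0.025
        assert asciminib.distribution.vss_target == 0.8

    @pytest.mark.parametrize("enzyme,vmax,km_u,fu_mic,fm", [
        ("CYP3A4", 3.8, 15.7, 0.160, 0.351),
        ("CYP2C8", 0.136, 7.6, 0.0829, 0.005),
        ("CYP2D6", 0.736, 30.7, 0.0680, 0.002),
        ("CYP2J2", 0.355, 0.694, 0.0925, 0.0076),
        ("UGT1A3", 1.73, 12.9, 0.0811, 0.033),
        ("UGT1A4", 0.73, 12.9, 0.0811, 0.033),
        ("UGT2B7", 2.04, 12.7, 0.0811, 0.131),
        ("UGT2B17", 17.7, 9.41, 0.0811, 0.076),
    ])
    def test_enzyme_block(self, asciminib, enzyme, vmax, km_u, fu_mic, fm):
        e = asciminib.enzyme(enzyme)
        assert (e.vmax, e.km_u, e.fu_mic, e.fm_target) == (vmax, km_u, fu_mic, fm)

    def test_transporter_and_elimination_block(self, asciminib):
        t = asciminib.transporters[0]
        assert t.transporter_id == "BCRP" and t.location == "liver canalicular"
        assert t.jmax == 0.2782
        assert t.km == 0.0070865
        assert t.cl_pd == 0.06
        assert t.ft_target_low_dose == 0.311
        assert asciminib.renal.cl_renal == 0.108
        assert asciminib.additional_clearance.hlm_clint_u == 0.65
        assert asciminib.additional_clearance.fm_target == 0.0071

    @pytest.mark.parametrize("target,ki", [
        ("CYP1A2", 10.4), ("CYP2A6", 43.6), ("CYP2B6", 2.62),
        ("CYP2C8", 0.466), ("CYP2C9", 0.03), ("CYP2C9_in_vitro", 0.407),
        ("CYP2C19", 1.5), ("CYP2D6", 8.5), ("CYP2E1", 37.5),
        ("CYP3A4", 0.348), ("UGT1A1", 0.35), ("UGT2B7", 7.28),
        ("P-gp", 21.7), ("BCRP", 0.088), ("OATP1B1", 2.46), ("OATP1B3", 1.92),
        ("OAT1", 6.90), ("OAT3", 1.01), ("OCT1", 3.41), ("OCT2", 8.22),
        ("MATE1", 6.22), ("MATE2K", 2.36),
    ])
    def test_inhibition_block(self, asciminib, target, ki):
        assert asciminib.inhibition_for(target).ki_u == ki

    def test_induction_block(self, asciminib):
        cyp1a2 = asciminib.induction_for("CYP1A2")
        assert (cyp1a2.indc50, cyp1a2.indmax) == (0.59, 4.5)
        cyp3a4 = asciminib.induction_for("CYP3A4")
        assert (cyp3a4.indc50, cyp3a4.indmax) == (2.057, 1.53)
        assert cyp3a4.calibrated
        invitro = asciminib.induction_for("CYP3A4_in_vitro")
        assert (invitro.indc50, invitro.indmax) == (2.7, 5.4)

    def test_pathway_targets_sum_to_one(self, asciminib):
        total = (sum(e.fm_target for e in asciminib.enzymes)
                 + asciminib.transporters[0].ft_target_low_dose
                 + asciminib.renal.fe_target
                 + asciminib.additional_clearance.fm_target)
        assert abs(total - 1.0) <= 0.01


class TestConfigIO:
    def test_round_trip_is_lossless_for_every_fixture(self, tmp_path):
        for name in available_compounds():
            c = load_compound(name)
            path = tmp_path / f"{name}.yaml"
            save_compound(c, path)
            assert load_compound(path) == c

    def test_missing_mandatory_field_names_it(self):
        with pytest.raises(ValidationError, match="molecular_weight"):
            load_compound({"name": "x", "phys_chem": {"logp": 1.0},
                           "binding": {"fu_plasma": 0.1, "blood_to_plasma": 1.0}})

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValidationError):
            load_compound({"name": "x",
                           "phys_chem": {"molecular_weight": -1, "logp": 0},
                           "binding": {"fu_plasma": 0.1, "blood_to_plasma": 1.0}})

    def test_ionizable_class_requires_pka(self):
        with pytest.raises(ValidationError, match="pka"):
            load_compound({"name": "x",
                           "phys_chem": {"molecular_weight": 300, "logp": 1,
                                         "compound_class": "monoprotic base"},
                           "binding": {"fu_plasma": 0.1, "blood_to_plasma": 1.0}})

    def test_inconsistent_pathway_targets_rejected(self, asciminib):
        data = asciminib.model_dump(exclude_none=True)
        data["enzymes"][0]["fm_target"] = 0.9
        with pytest.raises(ValidationError, match="sum"):
            load_compound(data)

    def test_unknown_compound_name(self):
        with pytest.raises(FileNotFoundError):
            load_compound("nosuchdrug")


class TestInVitroConversions:
    @pytest.mark.parametrize("ic50,mode,kwargs,expected", [
        (20.8, "half", {}, 10.4),                                  # CYP1A2
        (0.56, "substrate-corrected", {"s": 10, "km_probe": 16.8}, 0.3511),
        (7.28, "direct", {}, 7.28),                                # UGT2B7
        (5.0, "substrate-corrected", {"s": 0, "km_probe": 16.8}, 5.0),
    ])
    def test_ki_from_ic50_examples(self, ic50, mode, kwargs, expected):
        assert ki_from_ic50(ic50, mode, **kwargs) == pytest.approx(expected, abs=1e-3)

    def test_ugt1a1_cheng_prusoff_rounds_to_printed_value(self):
        assert round(ki_from_ic50(0.56, "substrate-corrected", s=10.0,
                                  km_probe=16.8), 2) == 0.35

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            ki_from_ic50(0.0, "half")
        with pytest.raises(ValueError):
            ki_from_ic50(1.0, "substrate-corrected", s=1.0, km_probe=0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ic50=st.floats(0.01, 100), s=st.floats(0, 50),
           s2=st.floats(0, 50), factor=st.floats(1.01, 10))
    def test_ki_monotone_in_ic50_and_antitone_in_substrate(self, ic50, s, s2,
                                                           factor):
        km = 16.8
        assert ki_from_ic50(ic50 * factor, "substrate-corrected", s=s,
                            km_probe=km) > ki_from_ic50(ic50,
                                                        "substrate-corrected",
                                                        s=s, km_probe=km)
        lo, hi = sorted((s, s2))
        assert ki_from_ic50(ic50, "substrate-corrected", s=hi, km_probe=km) \
            <= ki_from_ic50(ic50, "substrate-corrected", s=lo, km_probe=km)

    def test_km_unbound_identity_and_inversion(self):
        assert km_unbound(98.125, 1.0) == 98.125
        # CYP3A4: apparent Km 98.125 µM with fu_mic 0.160 gives the printed
        # unbound value, and the inversion recovers the apparent constant
        km_u = km_unbound(98.125, 0.160)
        assert km_u == pytest.approx(15.7, abs=1e-9)
        assert km_u / 0.160 == pytest.approx(98.125)

    def test_km_unbound_degenerate_binding_rejected(self):
        with pytest.raises(ValueError):
            km_unbound(10.0, 0.0)
        with pytest.raises(ValueError):
            km_unbound(10.0, 1.2)
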