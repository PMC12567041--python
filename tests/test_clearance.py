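"""Pathway-fraction bookkeeping and the retrograde clearance model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ascipk.clearance import (PathwayFractions, bcrp_fraction,
                              partition_clearance, renal_fraction_check,
                              retrograde_vmax)
from ascipk.units import ml_min_to_l_h

UGT_SPLITS = {"UGT1A3/4": 0.242, "UGT2B7": 0.479, "UGT2B17": 0.279}
CYP_FMS = {"CYP3A4": 0.351, "CYP2C8": 0.005, "CYP2D6": 0.002, "CYP2J2": 0.0076}


class TestBcrpFraction:
    def test_published_clearance_pair(self):
        """CL/F 4.96 without vs 7.19 L/h with the transporter gives the
        ~31% biliary fraction (30.99% carried unrounded)."""
        ft = bcrp_fraction(7.19, 4.96)
        assert ft == pytest.approx(0.3102, abs=5e-4)
        assert round(100 * ft) == 31

    def test_degenerate_and_forced_cases(self):
        assert bcrp_fraction(5.0, 5.0) == 0.0
        assert bcrp_fraction(10.0, 5.0) == 0.5

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            bcrp_fraction(4.0, 5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(1.0, 50.0), gap=st.floats(0.0, 0.9),
           k=st.floats(0.1, 100.0))
    def test_scale_invariance(self, a, gap, k):
        b = a * (1.0 - gap)
        assert bcrp_fraction(k * a, k * b) == pytest.approx(bcrp_fraction(a, b))


class TestPartitionClearance:
    def test_revised_ugt_split_reproduces_final_fm_values(self):
        """58.3% UGT total minus the biliary fraction, split 24.2/47.9/27.9,
        lands on the final ~6.6 / 13.1 / 7.6% contributions."""
        ft = bcrp_fraction(7.19, 4.96)
        pf = partition_clearance(0.583, ft, UGT_SPLITS, CYP_FMS,
                                 fe=0.044, f_hyd=0.0071)
        assert pf.fm["UGT2B7"] == pytest.approx(0.1308, abs=3e-4)
        assert round(100 * pf.fm["UGT2B7"], 1) == 13.1
        assert pf.fm["UGT1A3/4"] == pytest.approx(0.066, abs=1e-3)
        assert pf.fm["UGT2B17"] == pytest.approx(0.076, abs=1e-3)
        assert abs(pf.total - 1.0) <= 0.01

    def test_no_transporter_limit(self):
        pf = partition_clearance(0.583, 0.0, UGT_SPLITS, CYP_FMS,
                                 fe=0.044, f_hyd=0.0071)
        for u, s in UGT_SPLITS.items():
            assert pf.fm[u] == pytest.approx(0.583 * s)

    def test_transporter_exceeding_ugt_total_rejected(self):
        with pytest.raises(ValueError):
            partition_clearance(0.3, 0.4, UGT_SPLITS, CYP_FMS, 0.044, 0.0071)

    def test_split_ordering_invariance(self):
        ft = 0.311
        a = partition_clearance(0.583, ft, UGT_SPLITS, CYP_FMS, 0.044, 0.0071)
        reversed_splits = dict(reversed(list(UGT_SPLITS.items())))
        b = partition_clearance(0.583, ft, reversed_splits, CYP_FMS,
                                0.044, 0.0071)
        assert a.fm == b.fm

    def test_fractions_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            partition_clearance(1.2, 0.3, UGT_SPLITS, CYP_FMS, 0.044, 0.0071)
        with pytest.raises(ValueError):
            PathwayFractions(fm={"CYP3A4": 0.5})  # sums to 0.5, not 1


class TestRenalChecks:
    def test_filtration_ratio_of_measured_renal_clearance(self):
        """1.8 mL/min against fu_p × GFR = 0.027 × 120 gives ~56%."""
        ratio = renal_fraction_check(1.8, 0.027, 120.0)
        assert ratio == pytest.approx(0.5556, abs=1e-3)

    def test_filtration_only_drug(self):
        assert renal_fraction_check(3.24, 0.027, 120.0) == pytest.approx(1.0)

    def test_unit_conversion_to_l_per_h(self):
        assert ml_min_to_l_h(1.8) == pytest.approx(0.108)


class TestRetrogradeModel:
    def _fractions(self):
        return PathwayFractions(
            fm={"CYP3A4": 0.351, "CYP2C8": 0.005, "CYP2D6": 0.002,
                "CYP2J2": 0.0076, "UGT1A3": 0.033, "UGT1A4": 0.033,
                "UGT2B7": 0.131, "UGT2B17": 0.076},
            ft={"BCRP": 0.311}, fe_renal=0.044, f_hydrolysis=0.0071)

    def _km(self, asciminib):
        return {e.enzyme_id: e.km_u for e in asciminib.enzymes}

    def test_null_pathway_gives_zero_vmax(self, asciminib, subject):
        fr = self._fractions()
        fr.fm["CYP2C8"] = 0.0
        fr.fm["CYP3A4"] += 0.005
        vmax = retrograde_vmax(fr, 7.19, self._km(asciminib), subject)
        assert vmax["CYP2C8"] == 0.0

    def test_vmax_linear_in_clearance_target(self, asciminib, subject):
        fr = self._fractions()
        v1 = retrograde_vmax(fr, 3.0, self._km(asciminib), subject)
        v2 = retrograde_vmax(fr, 6.0, self._km(asciminib), subject)
        for enz in v1:
            assert v2[enz] == pytest.approx(2 * v1[enz], rel=0.02)

    def test_cyp3a4_vmax_near_published_scale(self, asciminib, subject):
        """Back-calculated CYP3A4 Vmax should land within the hepatic
        abundance uncertainty of the published 3.8 pmol/min/pmol (exact
        agreement is not expected across abundance assumptions)."""
        vmax = retrograde_vmax(self._fractions(), 7.19, self._km(asciminib),
                               subject)
        assert 3.8 / 3.0 <= vmax["CYP3A4"] <= 3.8 * 3.0

    def test_missing_abundance_rejected(self, asciminib, subject):
        fr = self._fractions()
        fr.fm["CYP9Z9"] = 0.0076
        fr.fm["CYP2J2"] = 0.0
        km = self._km(asciminib)
        km["CYP9Z9"] = 1.0
        with pytest.raises(ValueError, match="abundance"):
            retrograde_vmax(fr, 7.19, km, subject)


class TestForwardSimulationFixedPoint:
    def test_recovered_fractions_match_targets(self, asciminib, subject,
                                               calibration):
        """Retrograde then forward-simulate is a fixed point: the pathway
        fractions recovered from the 20 mg BID steady-state simulation match
        the targets within 2% absolute (CL/F bookkeeping for the
        transporter, flux shares for the rest)."""
        from ascipk.engine import (pathway_fractions_from_targets,
                                   recovered_pathway_fractions)
        rec = recovered_pathway_fractions(asciminib, subject, calibration)
        targets = pathway_fractions_from_targets(asciminib)
        expected = dict(targets.fm)
        expected["BCRP"] = targets.ft["BCRP"]
        expected["renal"] = targets.fe_renal
        expected["hydrolysis"] = targets.f_hydrolysis
        for pathway, target in expected.items():
            assert rec[pathway] == pytest.approx(target, abs=0.02), pathway

    def test_pathway_table_matches_pie_chart_categories(self, asciminib):
        from ascipk.engine import pathway_fractions_from_targets
        table = pathway_fractions_from_targets(asciminib).as_table()
        assert set(table.pathway) >= {"CYP3A4", "UGT2B7", "BCRP", "renal",
                                      "hydrolysis"}
        assert table.fraction.sum() == pytest.approx(1.0, abs=0.01)
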