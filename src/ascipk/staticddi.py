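"""Static (non-ODE) DDI risk metrics.

Implements the mechanistic-static Net Effect AUC-ratio model, the basic
induction screen R3, the relative induction score (RIS), and the in-vitro
→ in-vivo induction-parameter calibration against the rifampicin positive
control.  These are desk calculations operating on steady-state perpetrator
concentrations; the compartmental concentrations for a simulated regimen
are produced by the ODE engine (:func:`static_inputs_from_simulation`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .compounds import CompoundModel, InductionParam

# in-vivo rifampicin CYP3A4 induction reference implied by the calibrated
# asciminib pair (in vitro 2.7 µM / Indmax 5.4 calibrated to 2.057 µM /
# 1.53-fold against rifampicin in vitro EC50 0.42 µM, Emax 124):
# EC50_vivo = 0.42 * (2.057/2.7); Emax_vivo = 124 * (0.53/4.4)
RIFAMPICIN_INVITRO = InductionParam(target_id="CYP3A4", indc50=0.42,
                                    indmax=125.0, calibrated=False)
RIFAMPICIN_INVIVO = InductionParam(target_id="CYP3A4", indc50=0.32,
                                   indmax=15.94, calibrated=True)

# linear mapping from relative induction score to the expected percent AUC
# reduction of a sensitive substrate (documented regression constant; an
# RIS of 0.070 corresponds to about a 14% AUC reduction)
RIS_TO_PERCENT_AUC_REDUCTION = 200.0


@dataclass
class StaticAssessmentInput:
    """Perpetrator concentrations and victim structure for one enzyme."""

    fm: float                         # victim fraction metabolised by the enzyme
    fg: float = 1.0                   # victim fraction escaping gut metabolism
    imax_u_liver: float = 0.0         # µM unbound hepatic inlet
    igut: float = 0.0                 # µM enterocyte (total, guidance convention)
    imax_u_plasma: float = 0.0        # µM unbound systemic
    ki_u: Optional[float] = None      # reversible inhibition constant
    ki_u_gut: Optional[float] = None  # defaults to ki_u
    indc50: Optional[float] = None
    indmax: Optional[float] = None
    d_factor: float = 1.0             # induction scaling factor d
    tdi_b_liver: float = 1.0          # time-dependent-inhibition terms (unity
    tdi_b_gut: float = 1.0            # here: no apparent TDI in vitro)

    def __post_init__(self):
        if not (0.0 <= self.fm <= 1.0):
            raise ValueError("fm must be in [0, 1]")
        for name in ("imax_u_liver", "igut", "imax_u_plasma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class StaticAssessmentResult:
    enzyme: str
    aucr_static: float
    r3: Optional[float] = None
    ris: Optional[float] = None

    def __post_init__(self):
        if self.aucr_static <= 0:
            raise ValueError("AUCR must be positive")
        if self.r3 is not None and not (0.0 < self.r3 <= 1.0):
            raise ValueError("R3 must be in (0, 1]")


def _a_term(i: float, ki: Optional[float]) -> float:
    """Reversible-inhibition term A = 1 / (1 + I/Ki)."""
    if ki is None or i <= 0:
        return 1.0
    return 1.0 / (1.0 + i / ki)


def _c_term(i: float, indc50: Optional[float], indmax: Optional[float],
            d: float) -> float:
    """Induction term C = 1 + d·Emax·I/(EC50 + I), Emax = Indmax − 1."""
    if indc50 is None or indmax is None or i <= 0:
        return 1.0
    return 1.0 + d * (indmax - 1.0) * i / (indc50 + i)


def net_effect_aucr(inp: StaticAssessmentInput) -> float:
    """Mechanistic-static Net Effect AUC ratio for a probe substrate.

    AUCR = 1/[(Ag·Bg·Cg)·(1−Fg) + Fg] × 1/[(Ah·Bh·Ch)·fm + (1−fm)]
    with A the reversible-inhibition, B the inactivation (unity here) and
    C the induction terms in gut (g) and liver (h).
    """
    ki_gut = inp.ki_u_gut if inp.ki_u_gut is not None else inp.ki_u
    a_g = _a_term(inp.igut, ki_gut)
    c_g = _c_term(inp.igut, inp.indc50, inp.indmax, inp.d_factor)
    a_h = _a_term(inp.imax_u_liver, inp.ki_u)
    c_h = _c_term(inp.imax_u_liver, inp.indc50, inp.indmax, inp.d_factor)
    gut = (a_g * inp.tdi_b_gut * c_g) * (1.0 - inp.fg) + inp.fg
    liver = (a_h * inp.tdi_b_liver * c_h) * inp.fm + (1.0 - inp.fm)
    if liver <= 0 or gut <= 0:
        raise ZeroDivisionError(
            "net effect undefined: fm = 1 with complete inhibition leaves no "
            "residual clearance")
    return (1.0 / gut) * (1.0 / liver)


def r3(i: float, indc50: float, indmax: float, d: float = 1.0) -> float:
    """Basic static induction screen: R3 = 1/(1 + d·(Indmax−1)·I/(IndC50+I)).

    In (0, 1]; values below the guidance cutoff (0.8) flag induction risk.
    """
    if i < 0 or indc50 <= 0 or indmax < 1 or d <= 0:
        raise ValueError("inputs must be positive (indmax >= 1, i >= 0)")
    return 1.0 / (1.0 + d * (indmax - 1.0) * i / (indc50 + i))


def ris(emax: float, ec50: float, i_u: float) -> float:
    """Relative induction score: RIS = Emax·I_u/(EC50 + I_u).

    ``emax`` is the fold-increase over baseline (Indmax − 1); monotone
    increasing in the unbound perpetrator concentration.
    """
    if emax <= 0 or ec50 <= 0:
        raise ValueError("emax and ec50 must be positive")
    if i_u < 0:
        raise ValueError("i_u must be >= 0")
    return emax * i_u / (ec50 + i_u)


def ris_to_auc_reduction_percent(ris_value: float) -> float:
    """Map an RIS to the expected percent AUC reduction of a sensitive
    substrate via the documented linear regression."""
    return min(RIS_TO_PERCENT_AUC_REDUCTION * ris_value, 100.0)


def calibrate_induction(test_invitro: InductionParam,
                        ref_invitro: InductionParam = RIFAMPICIN_INVITRO,
                        ref_invivo: InductionParam = RIFAMPICIN_INVIVO,
                        ) -> InductionParam:
    """Scale in-vitro induction parameters by the positive-control ratio.

    IndC50_cal = IndC50_test × (EC50_ref,vivo / EC50_ref,vitro)
    Emax_cal   = Emax_test  × (Emax_ref,vivo / Emax_ref,vitro)
    Indmax_cal = Emax_cal + 1.  Identity when the reference in vivo equals
    the reference in vitro.
    """
    for ref in (ref_invitro, ref_invivo):
        if ref.indc50 <= 0 or ref.indmax <= 1:
            raise ValueError("reference induction parameters must be positive")
    indc50 = test_invitro.indc50 * ref_invivo.indc50 / ref_invitro.indc50
    emax = (test_invitro.indmax - 1.0) * (ref_invivo.indmax - 1.0) / \
        (ref_invitro.indmax - 1.0)
    return InductionParam(target_id=test_invitro.target_id, indc50=indc50,
                          indmax=emax + 1.0, calibrated=True)


# ---------------------------------------------------------------------------
# Engine-coupled helpers
# ---------------------------------------------------------------------------

def static_inputs_from_simulation(t, conc_ng_ml, compound: CompoundModel,
                                  dose_mg: float, tau_h: float,
                                  q_hepatic: float = 80.0,
                                  q_ent: float = 18.0) -> dict[str, float]:
    """Guidance-convention perpetrator concentrations from a steady-state
    simulated profile.

    Hepatic inlet (unbound): fu·(Cmax + Fa·Fg·ka·Dose/Q_h/RB);
    enterocyte (total):  Fa·ka·Dose/Q_ent;  systemic (unbound): fu·Cmax.
    """
    mw = compound.phys_chem.molecular_weight
    cmax = float(np.max(conc_ng_ml)) / mw        # µM total plasma
    a = compound.absorption
    fu = compound.binding.fu_plasma
    rb = compound.binding.blood_to_plasma
    dose_um = dose_mg * 1000.0 / mw
    fg = a.q_gut / (a.q_gut + a.fu_gut * a.gut_clint_u)
    i_liver = fu * (cmax + a.fa * fg * a.ka * dose_um / (q_hepatic * rb))
    igut = a.fa * a.ka * dose_um / q_ent
    return {"imax_u_liver": i_liver, "igut": igut, "imax_u_plasma": fu * cmax,
            "cmax_u": fu * cmax}


# victim-probe structure used by the basic static screen (sensitive
# substrates: fm of the probe for each enzyme, Fg for CYP3A4 via midazolam)
PROBE_STRUCTURE = {
    "CYP3A4": {"fm": 0.94, "fg": 0.62},
    "CYP2C9": {"fm": 0.91, "fg": 1.0},
    "CYP2C8": {"fm": 0.70, "fg": 1.0},
    "CYP2C19": {"fm": 0.87, "fg": 1.0},
    "CYP1A2": {"fm": 0.90, "fg": 1.0},
    "UGT1A1": {"fm": 0.90, "fg": 1.0},
}


def static_screen(perpetrator: CompoundModel, concentrations: dict[str, float],
                  enzymes: tuple[str, ...] = ("CYP3A4", "CYP2C9", "CYP2C8"),
                  use_in_vitro_ki: bool = True) -> pd.DataFrame:
    """Net-effect AUCR screen across probe enzymes plus R3/RIS flags.

    ``use_in_vitro_ki`` selects the pre-optimisation in-vitro inhibition
    constants where a separate in-vitro entry exists (the initial risk
    screen predates the top-down refinements).  Flags use the 0.8 / 1.25
    no-effect bounds.
    """
    rows = []
    for enzyme in enzymes:
        probe = PROBE_STRUCTURE[enzyme]
        ki = None
        if use_in_vitro_ki:
            p = perpetrator.inhibition_for(f"{enzyme}_in_vitro")
            if p is not None:
                ki = p.ki_u
        if ki is None:
            p = perpetrator.inhibition_for(enzyme)
            ki = p.ki_u if p else None
        ind = perpetrator.induction_for(enzyme)
        inp = StaticAssessmentInput(
            fm=probe["fm"], fg=probe["fg"],
            imax_u_liver=concentrations["imax_u_liver"],
            igut=concentrations["igut"],
            imax_u_plasma=concentrations["imax_u_plasma"],
            ki_u=ki,
            indc50=ind.indc50 if ind else None,
            indmax=ind.indmax if ind else None)
        aucr = net_effect_aucr(inp)
        r3_val = (r3(concentrations["imax_u_liver"], ind.indc50, ind.indmax)
                  if ind else None)
        rows.append({"enzyme": enzyme, "mechanism": "net-effect",
                     "aucr_static": aucr, "r3": r3_val,
                     "flag": aucr > 1.25 or aucr < 0.8})
    return pd.DataFrame(rows)
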