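"""Pathway-fraction bookkeeping and the retrograde clearance model.

The elimination of asciminib is described by fractional pathway
contributions to total apparent clearance: fm per metabolic enzyme, ft for
the BCRP-mediated biliary route, fe for renal excretion, and a fixed
hydrolysis share.  The hADME-derived UGT total is revised downward by the
BCRP fraction (estimated from simulated CL/F with and without the
transporter) before being split across the individual UGT isoforms.

The retrograde model then converts a whole-body oral clearance target plus
the pathway fractions into enzyme-level intrinsic clearances and Vmax
values for a given subject's enzyme abundances, inverting the well-stirred
liver model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .population import SubjectPhysiology

UGT_IDS = ("UGT1A3", "UGT1A4", "UGT2B7", "UGT2B17")


@dataclass
class PathwayFractions:
    """Fractions of total apparent clearance per elimination route."""

    fm: dict[str, float] = field(default_factory=dict)   # per enzyme
    ft: dict[str, float] = field(default_factory=dict)   # per transporter
    fe_renal: float = 0.0
    f_hydrolysis: float = 0.0

    def __post_init__(self):
        for label, value in self.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"fraction {label} = {value} outside [0, 1]")
        if abs(self.total - 1.0) > 0.01:
            raise ValueError(f"pathway fractions sum to {self.total:.4f}, expected 1 ± 0.01")

    def items(self):
        yield from self.fm.items()
        yield from self.ft.items()
        yield "renal", self.fe_renal
        yield "hydrolysis", self.f_hydrolysis

    @property
    def total(self) -> float:
        return sum(v for _, v in self.items())

    def as_table(self):
        """Pathway-contribution table (pie-chart categories)."""
        import pandas as pd
        rows = [{"pathway": k, "fraction": v, "percent": 100.0 * v}
                for k, v in self.items()]
        return pd.DataFrame(rows)


def bcrp_fraction(clf_with: float, clf_without: float) -> float:
    """Transporter fraction of clearance from a with/without CL/F pair.

    ft = 1 − CL/F(no BCRP) / CL/F(with BCRP);  e.g. (7.19, 4.96) → 0.310.
    Scale invariant: bcrp_fraction(k·a, k·b) == bcrp_fraction(a, b).
    """
    if not (clf_with >= clf_without > 0):
        raise ValueError("need clf_with >= clf_without > 0")
    return 1.0 - clf_without / clf_with


def partition_clearance(
    ugt_total: float,
    bcrp_ft: float,
    ugt_splits: dict[str, float],
    cyp_fms: dict[str, float],
    fe: float,
    f_hyd: float,
) -> PathwayFractions:
    """Revise the UGT total for biliary excretion and split it per isoform.

    The biliary (BCRP) fraction is subtracted from the hADME-derived total
    UGT contribution; the remainder is apportioned by the relative in vitro
    UGT splits.  CYP fractions, renal and hydrolysis shares pass through
    unchanged.  The result must sum to 1 within 0.01.
    """
    for name, x in [("ugt_total", ugt_total), ("bcrp_ft", bcrp_ft),
                    ("fe", fe), ("f_hyd", f_hyd)]:
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"{name} outside [0, 1]")
    if bcrp_ft > ugt_total:
        raise ValueError("BCRP fraction exceeds the UGT total it is deducted from")
    split_sum = sum(ugt_splits.values())
    if abs(split_sum - 1.0) > 1e-6:
        raise ValueError(f"ugt_splits sum to {split_sum}, expected 1")
    revised_ugt = ugt_total - bcrp_ft
    fm = {u: revised_ugt * s for u, s in ugt_splits.items()}
    fm.update(cyp_fms)
    return PathwayFractions(fm=fm, ft={"BCRP": bcrp_ft}, fe_renal=fe,
                            f_hydrolysis=f_hyd)


def renal_fraction_check(cl_renal: float, fu_plasma: float, gfr: float) -> float:
    """Renal clearance as a fraction of filtration clearance fu_p × GFR.

    All inputs in matching units (e.g. mL/min/1.73 m²).  A ratio below 1 is
    consistent with net reabsorption / no transporter involvement.
    """
    if cl_renal <= 0 or fu_plasma <= 0 or gfr <= 0:
        raise ValueError("inputs must be positive")
    return cl_renal / (fu_plasma * gfr)


# ---------------------------------------------------------------------------
# Retrograde model
# ---------------------------------------------------------------------------

def hepatic_intrinsic_from_oral_clearance(
    oral_clearance: float,
    fa: float,
    fg: float,
    fu_blood: float,
    q_hepatic: float,
    hepatic_fraction: float,
    renal_fraction: float,
) -> float:
    """Total unbound hepatic intrinsic clearance implied by a CL/F target.

    Inverts CL/F = (CL_H + CL_R) / (fa · Fg · Fh) with the well-stirred
    relations CL_H = Q·fu_b·CLint/(Q + fu_b·CLint), Fh = 1 − CL_H/Q, and
    CL_R = renal_fraction · CL_systemic.  Returns CLint,u in L/h (blood
    flow basis ``q_hepatic`` in L/h blood).
    """
    if oral_clearance <= 0:
        raise ValueError("oral clearance target must be positive")
    # systemic clearance fraction handled hepatically
    # CL/F = CL_sys / (fa Fg Fh); CL_sys = CL_H / hepatic_fraction_of_systemic
    # solve for CL_H via fixed point on Fh (converges in a few iterations)
    fh = 0.95
    for _ in range(50):
        cl_sys = oral_clearance * fa * fg * fh
        cl_h = cl_sys * hepatic_fraction / (hepatic_fraction + renal_fraction)
        e = cl_h / q_hepatic
        if e >= 1.0:
            raise ValueError("implied hepatic extraction exceeds liver blood flow")
        fh_new = 1.0 - e
        if abs(fh_new - fh) < 1e-12:
            fh = fh_new
            break
        fh = fh_new
    clint = q_hepatic * e / (fu_blood * (1.0 - e))
    return clint


def retrograde_vmax(
    fractions: PathwayFractions,
    oral_clearance_target: float,
    km_u: dict[str, float],
    subject: SubjectPhysiology,
    fa: float = 0.96,
    fg: float = 0.83,
    fu_blood: float = 0.03375,
) -> dict[str, float]:
    """Back-calculate per-enzyme Vmax (pmol/min/pmol enzyme) from fm targets.

    The hepatic intrinsic clearance implied by the oral clearance target is
    apportioned across metabolic pathways by their fm; each enzyme's
    intrinsic clearance is converted to a per-pmol value using the subject's
    microsomal scaling (MPPGL × liver mass × abundance), and Vmax is the
    product of the per-pmol CLint,u and Km,u.  Vmax scales linearly with the
    oral clearance target.  Printed Vmax values from other platforms differ
    by their assumed abundances, so agreement is expected only within the
    abundance uncertainty.
    """
    hepatic_fraction = sum(fractions.fm.values()) + sum(fractions.ft.values()) \
        + fractions.f_hydrolysis
    clint_total = hepatic_intrinsic_from_oral_clearance(
        oral_clearance_target, fa, fg, fu_blood, subject.liver_blood_flow,
        hepatic_fraction, fractions.fe_renal)
    mg_protein = subject.mppgl * subject.liver_mass  # mg microsomal protein
    vmax: dict[str, float] = {}
    for enzyme, fm in fractions.fm.items():
        if fm == 0.0:
            vmax[enzyme] = 0.0
            continue
        abundance = subject.enzyme_abundance.get(enzyme, 0.0)
        if abundance <= 0:
            raise ValueError(f"zero abundance for enzyme {enzyme} with fm > 0")
        if enzyme not in km_u or km_u[enzyme] <= 0:
            raise ValueError(f"missing or non-positive Km,u for {enzyme}")
        clint_e = clint_total * fm / hepatic_fraction          # L/h, whole liver
        clint_per_pmol = clint_e * 1e6 / 60.0 / (mg_protein * abundance)  # µL/min/pmol
        vmax[enzyme] = clint_per_pmol * km_u[enzyme]           # pmol/min/pmol
    return vmax


def intrinsic_clearances(
    fractions: PathwayFractions,
    oral_clearance_target: float,
    subject: SubjectPhysiology,
    fa: float = 0.96,
    fg: float = 0.83,
    fu_blood: float = 0.03375,
) -> dict[str, float]:
    """Whole-liver unbound intrinsic clearance per pathway (L/h).

    Same apportioning as :func:`retrograde_vmax` but kept on the whole-organ
    scale, plus the implied systemic renal clearance meeting the fe target.
    Keys: each enzyme, ``hydrolysis``, and ``renal``.
    """
    hepatic_fraction = sum(fractions.fm.values()) + sum(fractions.ft.values()) \
        + fractions.f_hydrolysis
    clint_total = hepatic_intrinsic_from_oral_clearance(
        oral_clearance_target, fa, fg, fu_blood, subject.liver_blood_flow,
        hepatic_fraction, fractions.fe_renal)
    out = {enz: clint_total * fm / hepatic_fraction for enz, fm in fractions.fm.items()}
    out["hydrolysis"] = clint_total * fractions.f_hydrolysis / hepatic_fraction
    # systemic renal clearance consistent with the fe bookkeeping:
    # recover Fh from the total intrinsic clearance, then CL_sys = CL/F·fa·Fg·Fh
    e = fu_blood * clint_total / (subject.liver_blood_flow + fu_blood * clint_total)
    cl_sys = oral_clearance_target * fa * fg * (1.0 - e)
    out["renal"] = cl_sys * fractions.fe_renal / (hepatic_fraction + fractions.fe_renal)
    return out
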