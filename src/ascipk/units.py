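"""Small unit-conversion helpers.

Internal convention throughout the package: concentrations in µM, amounts in
µmol, time in h, volumes in L, body mass in kg.  Mass-based quantities
(doses in mg, plasma concentrations in ng/mL) are converted at the reporting
boundary using the compound's molecular weight.
"""

from __future__ import annotations

ML_PER_MIN_TO_L_PER_H = 60.0 / 1000.0
UL_PER_MIN_TO_L_PER_H = 60.0 / 1e6


def mg_to_umol(dose_mg: float, molecular_weight: float) -> float:
    """Convert a dose in mg to µmol (MW in g/mol)."""
    return dose_mg * 1000.0 / molecular_weight


def umol_to_mg(amount_umol: float, molecular_weight: float) -> float:
    return amount_umol * molecular_weight / 1000.0


def uM_to_ng_per_ml(conc_um, molecular_weight: float):
    """µM -> ng/mL.  1 µM = MW ng/mL."""
    return conc_um * molecular_weight / 1.0


def ng_per_ml_to_uM(conc_ng_ml, molecular_weight: float):
    return conc_ng_ml / molecular_weight


def ml_min_to_l_h(cl_ml_min: float) -> float:
    """mL/min -> L/h (e.g. renal clearance 1.8 mL/min = 0.108 L/h)."""
    return cl_ml_min * ML_PER_MIN_TO_L_PER_H
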