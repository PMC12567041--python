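"""Compound parameterisation: domain types, validation, and config I/O.

A :class:`CompoundModel` holds everything the simulator needs to know about
one drug: physicochemistry, blood binding, absorption, distribution,
enzyme/transporter kinetics, renal clearance, and interaction (inhibition /
induction) constants.  The fully mechanistic whole-body model is used for
the compound of interest (asciminib); co-administered perpetrator and probe
substrate drugs are represented by reduced compartmental stand-ins
(:class:`ReducedPK`) carrying their interaction constants and pathway
fractions.

Configs are plain YAML, one file per compound, with a schema version tag.
All concentrations are µM, times h, volumes L (see :mod:`ascipk.units`).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1

_IONIZABLE = {"monoprotic base", "monoprotic acid", "diprotic base", "diprotic acid"}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhysChem(_Strict):
    molecular_weight: float = Field(gt=0, description="g/mol")
    logp: float
    compound_class: str = "neutral"
    pka: Optional[float] = None

    @model_validator(mode="after")
    def _pka_required_if_ionizable(self):
        if self.compound_class in _IONIZABLE:
            if self.pka is None or not math.isfinite(self.pka):
                raise ValueError("pka must be finite for ionizable compound_class")
        return self


class BloodBinding(_Strict):
    fu_plasma: float = Field(gt=0, le=1)
    fu_plasma_renal_impaired: Optional[float] = Field(default=None, gt=0, le=1)
    blood_to_plasma: float = Field(gt=0)


class AbsorptionParams(_Strict):
    """First-order absorption with a Q_gut-type intestinal first pass.

    ``fa`` is the effective absorbed fraction entering the gut wall,
    ``gut_clint_u`` the unbound intestinal (CYP3A4) intrinsic clearance of
    the Q_gut model, so Fg = Q_gut / (Q_gut + fu_gut * gut_clint_u).
    """

    fa: float = Field(gt=0, le=1)
    fa_cv: float = Field(default=0.0, ge=0, description="percent")
    ka: float = Field(gt=0, description="1/h")
    ka_cv: float = Field(default=0.0, ge=0)
    tlag: float = Field(default=0.0, ge=0, description="h")
    fu_gut: float = Field(gt=0, le=1)
    q_gut: float = Field(gt=0, description="L/h")
    q_gut_cv: float = Field(default=0.0, ge=0)
    gut_clint_u: float = Field(default=0.0, ge=0, description="L/h, unbound")
    peff_human: Optional[float] = Field(default=None, description="1e-4 cm/s, informational")


class DistributionParams(_Strict):
    kp_scalar: float = Field(gt=0)
    vss_target: float = Field(gt=0, description="L/kg, plasma-referenced")
    kp_method: Literal["tissue-composition-predicted", "uniform-tuned"] = "uniform-tuned"


ENZYME_IDS = (
    "CYP3A4", "CYP2C8", "CYP2D6", "CYP2J2",
    "UGT1A3", "UGT1A4", "UGT2B7", "UGT2B17",
)


class EnzymeKinetics(_Strict):
    enzyme_id: str
    vmax: float = Field(ge=0, description="pmol/min/pmol enzyme")
    km_u: float = Field(gt=0, description="µM unbound")
    fu_mic: float = Field(default=1.0, gt=0, le=1)
    fm_target: Optional[float] = Field(default=None, ge=0, le=1)


class TransporterKinetics(_Strict):
    transporter_id: str = "BCRP"
    location: str = "liver canalicular"
    jmax: float = Field(ge=0, description="pmol/min/10^6 cells")
    km: float = Field(gt=0, description="µM intracellular unbound")
    cl_pd: float = Field(gt=0, description="mL/min/10^6 hepatocytes, passive diffusion")
    ft_target_low_dose: Optional[float] = Field(default=None, ge=0, le=1)


class RenalParams(_Strict):
    cl_renal: float = Field(ge=0, description="L/h, plasma-referenced")
    fe_target: Optional[float] = Field(default=None, ge=0, le=1)


class AdditionalClearance(_Strict):
    hlm_clint_u: float = Field(ge=0, description="µL/min/mg microsomal protein")
    pathway_label: str = "hydrolysis"
    fm_target: Optional[float] = Field(default=None, ge=0, le=1)


class InhibitionParam(_Strict):
    """Reversible inhibition constant for one enzyme or transporter target."""

    target_id: str
    ki_u: float = Field(gt=0, description="µM unbound")
    ic50_u: Optional[float] = Field(default=None, gt=0)
    conversion: Literal["half", "substrate-corrected", "direct"] = "direct"


class InductionParam(_Strict):
    target_id: str
    indc50: float = Field(gt=0, description="µM")
    indmax: float = Field(ge=1, description="maximum fold induction (Emax + 1)")
    calibrated: bool = False


class ReducedPK(_Strict):
    """One-compartment oral PK stand-in for co-administered drugs.

    ``fm`` maps enzyme/transporter ids to the fraction of total clearance
    they mediate (used when the drug is a probe substrate); ``fg_baseline``
    is the baseline fraction escaping gut metabolism, with ``gut_fm_enzyme``
    naming the enzyme responsible for the gut extraction.
    ``liver_enrichment`` multiplies the unbound hepatic inlet concentration
    (e.g. OCT1-mediated hepatocyte uptake for imatinib).
    """

    ka: float = Field(gt=0, description="1/h")
    tlag: float = Field(default=0.0, ge=0)
    f_oral: float = Field(gt=0, le=1, description="systemic availability")
    v_central: float = Field(gt=0, description="L, plasma-referenced")
    cl: float = Field(gt=0, description="L/h systemic plasma clearance")
    fu_plasma: float = Field(gt=0, le=1)
    fu_gut: float = Field(default=1.0, gt=0, le=1)
    liver_enrichment: float = Field(default=1.0, gt=0)
    fm: dict[str, float] = Field(default_factory=dict)
    # optional enterocyte-site inhibition overrides (µM); a target absent
    # here falls back to the systemic Ki
    ki_gut: dict[str, float] = Field(default_factory=dict)
    fg_baseline: float = Field(default=1.0, gt=0, le=1)
    gut_fm_enzyme: Optional[str] = None
    q_gut: float = Field(default=18.0, gt=0, description="L/h, Q_gut for the victim Fg model")

    @model_validator(mode="after")
    def _fm_sums(self):
        total = sum(self.fm.values())
        if total > 1.0 + 1e-9:
            raise ValueError("reduced-PK fm fractions exceed 1")
        return self


class CompoundModel(_Strict):
    name: str
    schema_version: int = SCHEMA_VERSION
    phys_chem: PhysChem
    binding: BloodBinding
    absorption: Optional[AbsorptionParams] = None
    distribution: Optional[DistributionParams] = None
    enzymes: list[EnzymeKinetics] = Field(default_factory=list)
    transporters: list[TransporterKinetics] = Field(default_factory=list)
    renal: Optional[RenalParams] = None
    additional_clearance: Optional[AdditionalClearance] = None
    inhibition: list[InhibitionParam] = Field(default_factory=list)
    induction: list[InductionParam] = Field(default_factory=list)
    reduced_pk: Optional[ReducedPK] = None

    @model_validator(mode="after")
    def _pathway_targets_sum(self):
        targets = [e.fm_target for e in self.enzymes]
        targets += [t.ft_target_low_dose for t in self.transporters]
        if self.renal is not None:
            targets.append(self.renal.fe_target)
        if self.additional_clearance is not None:
            targets.append(self.additional_clearance.fm_target)
        if targets and all(t is not None for t in targets):
            total = sum(targets)
            if abs(total - 1.0) > 0.01:
                raise ValueError(
                    f"pathway fm/ft/fe targets sum to {total:.4f}, expected 1 ± 0.01"
                )
        return self

    # -- convenience accessors -------------------------------------------
    def enzyme(self, enzyme_id: str) -> EnzymeKinetics:
        for e in self.enzymes:
            if e.enzyme_id == enzyme_id:
                return e
        raise KeyError(enzyme_id)

    def inhibition_for(self, target_id: str) -> Optional[InhibitionParam]:
        for p in self.inhibition:
            if p.target_id == target_id:
                return p
        return None

    def induction_for(self, target_id: str) -> Optional[InductionParam]:
        for p in self.induction:
            if p.target_id == target_id:
                return p
        return None


# ---------------------------------------------------------------------------
# In-vitro constant conversions
# ---------------------------------------------------------------------------

def ki_from_ic50(
    ic50_u: float,
    conversion: str = "half",
    s: float = 0.0,
    km_probe: float | None = None,
) -> float:
    """Convert an unbound IC50 to an unbound Ki.

    ``half``                 : Ki,u = IC50,u / 2 (competitive, S = Km assumed)
    ``substrate-corrected``  : Ki,u = IC50,u / (1 + S / Km_probe)  (Cheng–Prusoff)
    ``direct``               : Ki,u = IC50,u
    """
    if ic50_u <= 0:
        raise ValueError("ic50_u must be positive")
    if conversion == "half":
        return ic50_u / 2.0
    if conversion == "substrate-corrected":
        if s < 0:
            raise ValueError("probe substrate concentration S must be >= 0")
        if km_probe is None or km_probe <= 0:
            raise ValueError("km_probe must be positive for substrate-corrected conversion")
        return ic50_u / (1.0 + s / km_probe)
    if conversion == "direct":
        return ic50_u
    raise ValueError(f"unknown conversion {conversion!r}")


def km_unbound(km_apparent: float, fu_mic: float) -> float:
    """Unbound Michaelis constant: Km,u = Km,app × fu_mic."""
    if not (0.0 < fu_mic <= 1.0):
        raise ValueError("fu_mic must be in (0, 1]")
    if km_apparent <= 0:
        raise ValueError("km_apparent must be positive")
    return km_apparent * fu_mic


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data" / "compounds"


def load_compound(source: str | Path | dict) -> CompoundModel:
    """Load and validate a compound config.

    ``source`` may be a mapping, a path to a YAML file, or the bare name of
    a compound shipped with the package (e.g. ``"asciminib"``).
    """
    if isinstance(source, dict):
        data = source
    else:
        path = Path(source)
        if not path.suffix:
            path = _DATA_DIR / f"{path.name}.yaml"
        if not path.exists():
            raise FileNotFoundError(f"no compound config at {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return CompoundModel.model_validate(data)


def save_compound(compound: CompoundModel, path: str | Path) -> None:
    """Write a compound config; ``load_compound(save_compound(x)) == x``."""
    data = compound.model_dump(exclude_none=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def available_compounds() -> list[str]:
    return sorted(p.stem for p in _DATA_DIR.glob("*.yaml"))
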