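"""Synthetic virtual population: subject physiology and sampling.

Generates virtual individuals carrying the physiological quantities the
whole-body model needs — organ volumes and blood flows, liver scalars,
hepatic enzyme/transporter abundances with log-normal between-subject
variability, glomerular filtration, and plasma-protein level — together
with hepatic (Child–Pugh) and renal impairment modifiers.  All central
values and coefficients of variation live in the versioned data file
``data/population.yaml``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

_DATA_PATH = Path(__file__).parent / "data" / "population.yaml"

with open(_DATA_PATH) as _fh:
    CONSTANTS = yaml.safe_load(_fh)

IMPAIRMENTS = ("none", "CP-A", "CP-B", "CP-C", "CP-C-ugt-modified",
               "RI-mild", "RI-moderate", "RI-severe")

GFR_REFERENCE = 120.0  # mL/min/1.73 m^2, typical young-adult value


@dataclass
class SubjectPhysiology:
    """One virtual individual (volumes L, flows L/h blood, masses g)."""

    age: float
    sex: str
    body_weight: float
    tissue_volumes: dict[str, float]
    tissue_blood_flows: dict[str, float]
    hepatic_artery_flow: float
    cardiac_output: float
    blood_volume: float
    hematocrit: float
    liver_volume: float
    liver_mass: float
    mppgl: float
    hepatocellularity: float
    enzyme_abundance: dict[str, float]
    transporter_activity_scalar: dict[str, float]
    gut_cyp3a4_activity: float
    gfr: float
    plasma_protein_scalar: float
    impairment: str = "none"
    # per-subject multiplicative PK variability terms (compound-level CVs are
    # applied at trial time through these slots)
    ka_scalar: float = 1.0
    fa_scalar: float = 1.0
    qgut_scalar: float = 1.0

    def __post_init__(self):
        for name, v in self.tissue_volumes.items():
            if v <= 0:
                raise ValueError(f"non-positive volume for {name}")
        for name, q in self.tissue_blood_flows.items():
            if q <= 0:
                raise ValueError(f"non-positive flow for {name}")
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")
        total_flow = sum(self.tissue_blood_flows.values()) + self.hepatic_artery_flow
        if total_flow > self.cardiac_output * 1.0001:
            raise ValueError("regional flows exceed cardiac output")

    @property
    def liver_blood_flow(self) -> float:
        """Total liver inflow: hepatic artery + portal (gut + spleen)."""
        return (self.hepatic_artery_flow
                + self.tissue_blood_flows["gut"]
                + self.tissue_blood_flows["spleen"])


@dataclass
class PopulationSpec:
    base: str = "healthy"                 # healthy | cancer
    impairment: str = "none"
    age_range: tuple[float, float] = (20.0, 55.0)
    female_proportion: float = 0.5
    # optional per-quantity CV overrides (percent)
    variability_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (18 <= self.age_range[0] <= self.age_range[1] <= 99):
            raise ValueError("age_range must lie within adult bounds")
        if not (0.0 <= self.female_proportion <= 1.0):
            raise ValueError("female_proportion must be in [0, 1]")
        if self.base not in ("healthy", "cancer"):
            raise ValueError(f"unknown base population {self.base!r}")
        if self.impairment not in IMPAIRMENTS:
            raise ValueError(f"unknown impairment {self.impairment!r}")


def _lognormal(rng: np.random.Generator, mean: float, cv_percent: float) -> float:
    """Log-normal draw parameterised by arithmetic mean and CV%."""
    if cv_percent <= 0:
        return mean
    cv = cv_percent / 100.0
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def mean_subject(base: str = "healthy", sex: str = "male",
                 age: float = 35.0) -> SubjectPhysiology:
    """The deterministic central subject (all variability terms at 1)."""
    ref = CONSTANTS["reference"]["male"]
    subj = _build_subject(ref, sex="male", age=age, body_weight=ref["body_weight"],
                          scalars=None)
    if base == "cancer":
        subj = _apply_cancer(subj)
    return subj


def _build_subject(ref: dict, sex: str, age: float, body_weight: float,
                   scalars: Optional[dict]) -> SubjectPhysiology:
    """Assemble one subject from the reference tables."""
    liver_cfg = CONSTANTS["liver"]
    wscale = body_weight / ref["body_weight"]
    fscale = wscale ** 0.75

    volumes = {k: v * wscale for k, v in ref["tissue_volumes"].items()}
    flows = {k: q * fscale for k, q in ref["tissue_blood_flows"].items()}
    liver_volume = ref["liver_volume"] * wscale
    liver_mass = ref["liver_mass"] * wscale

    if sex == "female":
        fem = CONSTANTS["reference"]["female"]
        for k, s in fem.get("volume_scalars", {}).items():
            volumes[k] *= s
        liver_volume *= fem.get("liver_scalar", 1.0)
        liver_mass *= fem.get("liver_scalar", 1.0)

    s = scalars or {}
    abundances = {
        enz: spec["mean"] * s.get(f"abundance:{enz}", 1.0)
        for enz, spec in CONSTANTS["enzyme_abundance"].items()
    }
    transporters = {
        t: spec["mean"] * s.get(f"transporter:{t}", 1.0)
        for t, spec in CONSTANTS["transporters"].items()
    }

    return SubjectPhysiology(
        age=age,
        sex=sex,
        body_weight=body_weight,
        tissue_volumes=volumes,
        tissue_blood_flows=flows,
        hepatic_artery_flow=ref["hepatic_artery_flow"] * fscale,
        cardiac_output=ref["cardiac_output"] * fscale,
        blood_volume=ref["blood_volume"] * wscale,
        hematocrit=(CONSTANTS["reference"]["female"]["hematocrit"]
                    if sex == "female" else ref["hematocrit"]),
        liver_volume=liver_volume,
        liver_mass=liver_mass,
        mppgl=liver_cfg["mppgl"] * s.get("mppgl", 1.0),
        hepatocellularity=liver_cfg["hepatocellularity"] * s.get("hepatocellularity", 1.0),
        enzyme_abundance=abundances,
        transporter_activity_scalar=transporters,
        gut_cyp3a4_activity=s.get("gut_cyp3a4", 1.0),
        gfr=CONSTANTS["gfr"]["healthy_mean"] * s.get("gfr", 1.0),
        plasma_protein_scalar=s.get("plasma_protein", 1.0),
        ka_scalar=s.get("ka", 1.0),
        fa_scalar=s.get("fa", 1.0),
        qgut_scalar=s.get("qgut", 1.0),
    )


def _apply_cancer(subject: SubjectPhysiology) -> SubjectPhysiology:
    cfg = CONSTANTS["populations"]["cancer"]
    subj = copy.deepcopy(subject)
    subj.plasma_protein_scalar *= cfg["plasma_protein_scalar"]
    for enz in list(subj.enzyme_abundance):
        if enz.startswith("CYP"):
            subj.enzyme_abundance[enz] *= cfg["cyp_activity_scalar"]
    return subj


def sample_population(spec: PopulationSpec, n: int,
                      seed: int | np.random.Generator) -> list[SubjectPhysiology]:
    """Draw ``n`` virtual subjects; deterministic for a given seed.

    Healthy physiology is sampled first; impairment modifiers are applied
    afterwards so that an impaired subject and its demographically matched
    healthy control share all underlying random draws.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects = []
    for _ in range(n):
        subjects.append(_sample_one(spec, rng))
    return subjects


def _sample_one(spec: PopulationSpec, rng: np.random.Generator) -> SubjectPhysiology:
    demo = CONSTANTS["demographics"]
    sex = "female" if rng.random() < spec.female_proportion else "male"
    age = float(rng.uniform(*spec.age_range))
    ref = CONSTANTS["reference"]["male"]
    bw_mean = (CONSTANTS["reference"]["female"]["body_weight"]
               if sex == "female" else ref["body_weight"])
    body_weight = _lognormal(rng, bw_mean, demo["body_weight_cv"])

    liver_cfg = CONSTANTS["liver"]
    scalars: dict[str, float] = {
        "mppgl": _lognormal(rng, 1.0, liver_cfg["mppgl_cv"]),
        "hepatocellularity": _lognormal(rng, 1.0, liver_cfg["hepatocellularity_cv"]),
        "gfr": _lognormal(rng, 1.0, CONSTANTS["gfr"]["healthy_cv"]),
        "plasma_protein": _lognormal(rng, 1.0, CONSTANTS["plasma_protein"]["scalar_cv"]),
        "gut_cyp3a4": _lognormal(rng, 1.0, CONSTANTS["gut"]["cyp3a4_activity_cv"]),
    }
    for enz, espec in CONSTANTS["enzyme_abundance"].items():
        cv = spec.variability_overrides.get(enz, espec["cv"])
        scalars[f"abundance:{enz}"] = _lognormal(rng, 1.0, cv)
    for t, tspec in CONSTANTS["transporters"].items():
        scalars[f"transporter:{t}"] = _lognormal(rng, 1.0, tspec["cv"])

    subj = _build_subject(ref, sex=sex, age=age, body_weight=body_weight,
                          scalars=scalars)
    if spec.base == "cancer":
        subj = _apply_cancer(subj)
    if spec.impairment != "none":
        subj = apply_impairment(subj, spec.impairment, rng=rng)
    return subj


def apply_impairment(subject: SubjectPhysiology, impairment: str,
                     rng: np.random.Generator | None = None) -> SubjectPhysiology:
    """Return a copy of ``subject`` with organ-impairment modifiers applied.

    Child–Pugh classes scale functional liver mass, hepatic CYP abundance,
    hepatic/portal blood flow, plasma protein and GFR; the ugt-modified
    severe class additionally sets the reduced UGT1A4/UGT2B7 abundances.
    Renal bins place GFR inside the declared range (the bin midpoint when no
    generator is supplied).
    """
    if impairment == "none":
        return copy.deepcopy(subject)
    subj = copy.deepcopy(subject)
    subj.impairment = impairment

    if impairment.startswith("RI-"):
        lo, hi = CONSTANTS["renal_bins"][impairment]
        if rng is None:
            subj.gfr = 0.5 * (lo + hi)
        else:
            subj.gfr = float(rng.uniform(lo, hi * 0.999))
        return subj

    if impairment not in CONSTANTS["impairment"]:
        raise ValueError(f"unknown impairment {impairment!r}")
    mod = CONSTANTS["impairment"][impairment]
    subj.liver_mass *= mod["liver_mass"]
    subj.liver_volume *= mod["liver_mass"]
    for enz in list(subj.enzyme_abundance):
        if enz == "CYP3A4":
            subj.enzyme_abundance[enz] *= mod["cyp3a4_abundance"]
        elif enz.startswith("CYP"):
            subj.enzyme_abundance[enz] *= mod["other_cyp_abundance"]
        else:
            subj.enzyme_abundance[enz] *= mod["ugt_abundance"]
    for enz, value in mod.get("ugt_overrides", {}).items():
        base_mean = CONSTANTS["enzyme_abundance"][enz]["mean"]
        # preserve the subject's individual deviation around the new central value
        subj.enzyme_abundance[enz] *= value / base_mean
    flow_scale = mod["hepatic_flow"]
    subj.hepatic_artery_flow *= flow_scale
    subj.tissue_blood_flows["gut"] *= flow_scale
    subj.tissue_blood_flows["spleen"] *= flow_scale
    subj.plasma_protein_scalar *= mod["plasma_protein"]
    subj.gfr *= mod["gfr"]
    return subj
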