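"""Virtual-trial layer: regimens, study designs, PK metrics, ratio statistics.

A trial simulates n_trials × n_subjects virtual individuals.  DDI designs
are within-subject paired (each subject is simulated with and without the
perpetrator, with identical physiology), mirroring crossover clinical
designs; organ-impairment designs compare an impaired cohort against a
demographically matched healthy control cohort built from the same
underlying random draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compounds import CompoundModel
from .engine import Calibration, EngineOptions, PBPKSystem
from .population import (PopulationSpec, SubjectPhysiology, apply_impairment,
                         sample_population)


@dataclass
class Regimen:
    """Oral dosing regimen: dose in mg, schedule keyword, duration in days."""

    dose: float
    interval: str = "QD"     # QD | BID | TID | QID | single
    start_day: int = 1       # 1-based study day of the first dose
    n_days: int = 1

    _PER_DAY = {"QD": 1, "BID": 2, "TID": 3, "QID": 4, "single": 1}

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.interval not in self._PER_DAY:
            raise ValueError(f"unknown interval {self.interval!r}")

    @property
    def tau(self) -> float:
        """Dosing interval in hours."""
        return 24.0 / self._PER_DAY[self.interval]

    def dose_times(self, offset_h: float = 0.0) -> list[tuple[float, float]]:
        """(time h, dose mg) events; time 0 is the first study-day morning."""
        t0 = (self.start_day - 1) * 24.0 + offset_h
        if self.interval == "single":
            return [(t0, self.dose)]
        per_day = self._PER_DAY[self.interval]
        out = []
        for day in range(self.n_days):
            for k in range(per_day):
                out.append((t0 + day * 24.0 + k * self.tau, self.dose))
        return out


@dataclass
class TrialDesign:
    victim: Regimen
    perpetrator: Optional[Regimen] = None
    population: PopulationSpec = field(default_factory=PopulationSpec)
    n_trials: int = 10
    n_subjects: int = 10
    seed: int = 2024
    victim_offset_h: float = 0.0   # victim dose time relative to perpetrator dose
    washout_h: float = 96.0        # post-regimen follow-up for AUC_inf

    def __post_init__(self):
        if self.n_trials < 1 or self.n_subjects < 1:
            raise ValueError("n_trials and n_subjects must be >= 1")


@dataclass
class PKMetrics:
    auc_inf: Optional[float]     # ng·h/mL
    auc_tau: Optional[float]
    cmax: float                  # ng/mL
    tmax: float                  # h, relative to the analysed dose
    ctrough: Optional[float]
    auc_extrapolated_fraction: Optional[float] = None

    def __post_init__(self):
        for name in ("auc_inf", "auc_tau", "cmax", "ctrough"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RatioResult:
    geometric_mean_ratio: float
    ci90: tuple[float, float]
    metric: str
    n: int

    def __post_init__(self):
        lo, hi = self.ci90
        if not (lo <= self.geometric_mean_ratio <= hi):
            raise ValueError("CI must bracket the geometric mean ratio")


# ---------------------------------------------------------------------------
# Non-compartmental metrics
# ---------------------------------------------------------------------------

def pk_metrics(t: np.ndarray, conc: np.ndarray, dose_time: float,
               tau: Optional[float] = None,
               terminal_points: int = 8) -> PKMetrics:
    """Standard non-compartmental summaries of one concentration profile.

    ``t`` in hours, ``conc`` in ng/mL.  AUCs use the trapezoid on the dense
    grid; AUC_inf adds a log-linear terminal extrapolation from the last
    ``terminal_points`` positive samples.  If the terminal slope is not
    estimable (non-negative or ill-conditioned) AUC_inf is omitted.
    """
    mask = t >= dose_time - 1e-9
    tt, cc = t[mask], conc[mask]
    if len(tt) < 3:
        raise ValueError("profile does not cover the analysed interval")
    i_max = int(np.argmax(cc))
    cmax = float(cc[i_max])
    tmax = float(tt[i_max] - dose_time)
    auc_tau = ctrough = None
    if tau is not None:
        in_tau = tt <= dose_time + tau + 1e-9
        auc_tau = float(np.trapezoid(cc[in_tau], tt[in_tau]))
        ctrough = float(np.interp(dose_time + tau, tt, cc))
    auc_all = float(np.trapezoid(cc, tt))
    auc_inf = extrap = None
    if cc[-1] <= cmax * 1e-9:
        # profile fully decayed within the simulated window
        auc_inf, extrap = auc_all, 0.0
    else:
        tail_t, tail_c = tt[-terminal_points:], cc[-terminal_points:]
        pos = tail_c > 0
        if pos.sum() >= 3:
            slope, intercept = np.polyfit(tail_t[pos], np.log(tail_c[pos]), 1)
            if slope < -1e-9:
                k = -slope
                tail = float(cc[-1]) / k
                auc_inf = auc_all + tail
                extrap = tail / auc_inf
    return PKMetrics(auc_inf=auc_inf, auc_tau=auc_tau, cmax=cmax, tmax=tmax,
                     ctrough=ctrough, auc_extrapolated_fraction=extrap)


def summarize_metrics(metrics: Sequence[PKMetrics]) -> pd.DataFrame:
    """Population summary: mean, SD, CV% (median and range for Tmax)."""
    rows = []
    for name in ("cmax", "auc_inf", "auc_tau", "ctrough"):
        vals = np.array([getattr(m, name) for m in metrics
                         if getattr(m, name) is not None], dtype=float)
        if len(vals) == 0:
            continue
        rows.append({"metric": name, "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     "cv_percent": (100 * vals.std(ddof=1) / vals.mean()
                                    if len(vals) > 1 else 0.0),
                     "n": len(vals)})
    tmax = np.array([m.tmax for m in metrics])
    rows.append({"metric": "tmax", "median": float(np.median(tmax)),
                 "min": float(tmax.min()), "max": float(tmax.max()),
                 "n": len(tmax)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ratio statistics
# ---------------------------------------------------------------------------

def ddi_ratio(treated: Sequence[float], control: Sequence[float],
              paired: bool = True, metric: str = "AUC") -> RatioResult:
    """Geometric mean ratio with a 90% CI from t-statistics on log ratios.

    Non-positive entries are excluded with a warning.  For ``paired`` data
    the CI reflects within-subject log-ratio spread; otherwise a Welch
    two-sample interval on the log scale is used.
    """
    import warnings
    tr = np.asarray(treated, dtype=float)
    ct = np.asarray(control, dtype=float)
    if paired:
        if len(tr) != len(ct):
            raise ValueError("paired design needs matched arrays")
        ok = (tr > 0) & (ct > 0)
        if not ok.all():
            warnings.warn("excluding non-positive metric values")
        logr = np.log(tr[ok]) - np.log(ct[ok])
        n = len(logr)
        gmr = math.exp(logr.mean())
        if n > 1 and logr.std(ddof=1) > 0:
            half = stats.t.ppf(0.95, n - 1) * logr.std(ddof=1) / math.sqrt(n)
        else:
            half = 0.0
        ci = (gmr * math.exp(-half), gmr * math.exp(half))
        return RatioResult(gmr, ci, metric, n)
    tr = tr[tr > 0]
    ct = ct[ct > 0]
    lt, lc = np.log(tr), np.log(ct)
    diff = lt.mean() - lc.mean()
    se = math.sqrt(lt.var(ddof=1) / len(lt) + lc.var(ddof=1) / len(lc))
    df = len(lt) + len(lc) - 2
    half = stats.t.ppf(0.95, df) * se
    gmr = math.exp(diff)
    return RatioResult(gmr, (gmr * math.exp(-half), gmr * math.exp(half)),
                       metric, min(len(lt), len(lc)))


# ---------------------------------------------------------------------------
# Trial execution
# ---------------------------------------------------------------------------

def _simulate_arm(victim: CompoundModel, subject: SubjectPhysiology,
                  design: TrialDesign, perpetrator: Optional[CompoundModel],
                  calibration: Calibration, options: EngineOptions,
                  probe_mode: bool, dose_perpetrator: bool,
                  ) -> tuple[np.ndarray, np.ndarray, float, Optional[float]]:
    """One subject, one arm.

    The system always contains both compounds when a perpetrator is named;
    the control arm simply omits the perpetrator doses, so both arms share
    the same state layout and the paired comparison is exact.  Returns
    (t, analysed-drug conc in ng/mL, analysed dose time, tau or None).
    """
    perp_doses = (design.perpetrator.dose_times() if design.perpetrator else [])
    vic_doses = design.victim.dose_times(design.victim_offset_h)
    last = max(t for t, _ in vic_doses + perp_doses) if (vic_doses + perp_doses) \
        else 0.0
    duration = last + design.washout_h

    doses: dict[str, list[tuple[float, float]]] = {victim.name: vic_doses}
    if probe_mode:
        # the mechanistic compound acts as perpetrator on a reduced probe
        assert perpetrator is not None
        system = PBPKSystem(perpetrator, subject, options,
                            probes=[victim], calibration=calibration)
        if dose_perpetrator and perp_doses:
            doses[perpetrator.name] = perp_doses
    else:
        perps = [perpetrator] if perpetrator is not None else []
        system = PBPKSystem(victim, subject, options,
                            perpetrators=perps, calibration=calibration)
        if perpetrator is not None and dose_perpetrator and perp_doses:
            doses[perpetrator.name] = perp_doses
    res = system.simulate(doses, duration)
    conc = res.plasma_conc(victim.name)
    analysed_t0 = vic_doses[-1][0] if design.victim.interval != "single" \
        else vic_doses[0][0]
    tau = design.victim.tau if design.victim.interval != "single" else None
    return res.t, conc, analysed_t0, tau


def run_trial(design: TrialDesign, victim: CompoundModel,
              perpetrator: Optional[CompoundModel] = None,
              calibration: Calibration | None = None,
              options: EngineOptions | None = None,
              probe_mode: bool = False,
              subjects: Optional[Sequence[SubjectPhysiology]] = None,
              ) -> pd.DataFrame:
    """Run all subjects of a design, both arms when a perpetrator is given.

    Arms are within-subject paired: each subject is simulated with and
    without the perpetrator on identical physiology.  When every
    interaction mechanism is disabled the perpetrator cannot influence the
    victim, so the treated arm reuses the control trajectory and the paired
    ratio is exactly 1.  ``probe_mode`` flips the roles: the mechanistic
    compound acts as perpetrator and the analysed victim is a reduced probe
    substrate.

    Returns one row per subject and arm with the PK metrics.
    """
    calibration = calibration or Calibration()
    options = options or EngineOptions()
    if subjects is None:
        rng = np.random.default_rng(design.seed)
        subjects = sample_population(design.population,
                                     design.n_trials * design.n_subjects, rng)
    rows = []
    for i, subject in enumerate(subjects):
        t, conc, t0, tau = _simulate_arm(victim, subject, design, perpetrator,
                                         calibration, options, probe_mode,
                                         dose_perpetrator=False)
        m = pk_metrics(t, conc, t0, tau)
        rows.append({"subject": i, "trial": i // design.n_subjects,
                     "arm": "control", **m.__dict__})
        if perpetrator is not None:
            if options.interactions_enabled:
                t, conc, t0, tau = _simulate_arm(victim, subject, design,
                                                 perpetrator, calibration,
                                                 options, probe_mode,
                                                 dose_perpetrator=True)
                m = pk_metrics(t, conc, t0, tau)
            rows.append({"subject": i, "trial": i // design.n_subjects,
                         "arm": "treated", **m.__dict__})
    return pd.DataFrame(rows)


def trial_ratios(results: pd.DataFrame, metric: str = "auc_inf") -> RatioResult:
    """Paired geometric-mean ratio of a PK metric from run_trial output."""
    piv = results.pivot(index="subject", columns="arm", values=metric).dropna()
    return ddi_ratio(piv["treated"].values, piv["control"].values,
                     paired=True, metric=metric)


def oi_study(impairment: str, dose: float, victim: CompoundModel,
             calibration: Calibration | None = None,
             n_subjects: int = 10, seed: int = 2024,
             use_impaired_fu: bool = True,
             options: EngineOptions | None = None) -> dict[str, RatioResult]:
    """Organ-impairment study: impaired cohort vs matched healthy controls.

    Healthy subjects are sampled once; the impaired arm applies the organ
    modifiers to the same individuals, so demographics are matched exactly.
    For renal impairment the adjusted unbound plasma fraction is applied to
    the impaired arm when available (``use_impaired_fu``).
    Returns AUC_inf and Cmax ratio results.
    """
    calibration = calibration or Calibration()
    options = options or EngineOptions()
    rng = np.random.default_rng(seed)
    spec = PopulationSpec()
    healthy = sample_population(spec, n_subjects, rng)
    ri_rng = np.random.default_rng(seed + 1)
    impaired = [apply_impairment(s, impairment, rng=ri_rng) for s in healthy]

    victim_imp = victim
    if (impairment.startswith("RI-") and use_impaired_fu
            and victim.binding.fu_plasma_renal_impaired is not None):
        victim_imp = victim.model_copy(deep=True)
        victim_imp.binding.fu_plasma = victim.binding.fu_plasma_renal_impaired

    design = TrialDesign(victim=Regimen(dose=dose, interval="single"),
                         n_trials=1, n_subjects=n_subjects, seed=seed)
    out: dict[str, list[float]] = {"auc_c": [], "auc_i": [], "cmax_c": [], "cmax_i": []}
    for hc, im in zip(healthy, impaired):
        t, c, t0, tau = _simulate_arm(victim, hc, design, None, calibration,
                                      options, False, False)
        mc = pk_metrics(t, c, t0, tau)
        t, c, t0, tau = _simulate_arm(victim_imp, im, design, None, calibration,
                                      options, False, False)
        mi = pk_metrics(t, c, t0, tau)
        out["auc_c"].append(mc.auc_inf or np.nan)
        out["auc_i"].append(mi.auc_inf or np.nan)
        out["cmax_c"].append(mc.cmax)
        out["cmax_i"].append(mi.cmax)
    return {
        "AUC": ddi_ratio(out["auc_i"], out["auc_c"], paired=True, metric="AUC"),
        "Cmax": ddi_ratio(out["cmax_i"], out["cmax_c"], paired=True, metric="Cmax"),
    }
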