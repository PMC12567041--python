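"""Predictive-performance statistics: fold errors, Guest criteria, bounds.

Implements the standard PBPK verification metrics — signed percent
prediction error, average fold error (AFE), absolute average fold error
(AAFE), geometric mean fold error (GMFE) for ratio endpoints, the
twofold / 25% log-bounds, and the observed-ratio-scaled Guest acceptance
limits — together with loaders for the transcribed clinical verification
tables shipped with the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_OBS_DIR = Path(__file__).parent / "data" / "observed"

TWOFOLD_LOG_BOUND = math.log10(2.0)   # 0.301
BOUND_25_LOG = 0.097                  # 25% deviation bound on log10 R


@dataclass
class PredObsPair:
    predicted: float
    observed: float
    label: str = ""
    metric: str = "AUC"

    def __post_init__(self):
        if self.predicted <= 0 or self.observed <= 0:
            raise ValueError("predicted and observed must both be positive")

    @property
    def ratio(self) -> float:
        """R_pred/obs = model-predicted / clinically observed."""
        return self.predicted / self.observed


def percent_pe(predicted: float, observed: float) -> float:
    """Signed prediction error: [(predicted − observed)/observed] × 100."""
    if observed <= 0:
        raise ValueError("observed must be positive")
    return (predicted - observed) / observed * 100.0


def _clean(pairs: Sequence[PredObsPair]) -> list[PredObsPair]:
    ok = []
    for p in pairs:
        if p.predicted > 0 and p.observed > 0:
            ok.append(p)
        else:  # pragma: no cover - PredObsPair already validates
            warnings.warn(f"excluding non-positive pair {p.label}")
    if not ok:
        raise ValueError("no valid predicted/observed pairs")
    return ok


def afe_aafe(pairs: Sequence[PredObsPair]) -> tuple[float, float]:
    """Average and absolute average fold error.

    AFE = 10^(mean log10(pred/obs)); AAFE = 10^(mean |log10(pred/obs)|).
    AFE below/above 1 flags under-/over-prediction; AAFE ≥ max(AFE, 1/AFE).
    """
    logs = np.array([math.log10(p.ratio) for p in _clean(pairs)])
    return float(10.0 ** logs.mean()), float(10.0 ** np.abs(logs).mean())


def gmfe(pairs: Sequence[PredObsPair]) -> float:
    """Geometric mean fold error of ratio endpoints (identical in form to
    AAFE; used for DDI / organ-impairment ratio comparisons)."""
    logs = np.array([abs(math.log10(p.ratio)) for p in _clean(pairs)])
    return float(10.0 ** logs.mean())


def guest_limits(observed_ratio: float,
                 intra_subject_cv: float = 0.0) -> tuple[float, float]:
    """Observed-ratio-dependent acceptance interval for a DDI prediction.

    With the observed ratio oriented to R' ≥ 1 the bound factor is
    L = (δ + 2(R'−1)) / R', floored at the 1.25 no-effect bound so the
    limits never narrow below [0.8, 1.25] at R = 1.  δ widens with the
    allowed intra-subject variability following the standard log-scale
    equivalence-bound mapping δ = exp(1.116·CV/100): δ = 1 at CV 0 and
    δ = 1.25 at the conventional 20% CV.  Limits are symmetric under
    R → 1/R (reciprocal intervals).
    """
    import math as _math
    if observed_ratio <= 0:
        raise ValueError("observed_ratio must be positive")
    delta = _math.exp(1.116 * intra_subject_cv / 100.0)
    r = observed_ratio
    inverted = r < 1.0
    rp = 1.0 / r if inverted else r
    limit = max((delta + 2.0 * (rp - 1.0)) / rp, 1.25)
    lo, hi = rp / limit, rp * limit
    if inverted:
        lo, hi = 1.0 / hi, 1.0 / lo
    return lo, hi


def within_guest(predicted_ratio: float, observed_ratio: float,
                 intra_subject_cv: float = 0.0) -> bool:
    lo, hi = guest_limits(observed_ratio, intra_subject_cv)
    return lo <= predicted_ratio <= hi


def bounds_checks(pairs: Sequence[PredObsPair]) -> pd.DataFrame:
    """Twofold (|log10 R| < 0.301) and 25% (|log10 R| < 0.097) flags."""
    rows = []
    for p in pairs:
        lr = math.log10(p.ratio)
        rows.append({"label": p.label, "metric": p.metric, "ratio": p.ratio,
                     "log10_ratio": lr,
                     "within_twofold": abs(lr) < TWOFOLD_LOG_BOUND,
                     "within_25pct": abs(lr) < BOUND_25_LOG})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    pairs: list[PredObsPair]
    afe: float
    aafe: float
    table: pd.DataFrame

    @classmethod
    def from_pairs(cls, pairs: Sequence[PredObsPair]) -> "EvaluationReport":
        pairs = list(pairs)
        a, aa = afe_aafe(pairs)
        tab = bounds_checks(pairs)
        tab["percent_pe"] = [percent_pe(p.predicted, p.observed) for p in pairs]
        return cls(pairs=pairs, afe=a, aafe=aa, table=tab)


# ---------------------------------------------------------------------------
# Transcribed clinical verification tables
# ---------------------------------------------------------------------------

def load_pk_table() -> pd.DataFrame:
    """Observed and simulated PK summaries (Cmax, AUC, Ctrough, Tmax) for
    the single-dose healthy-volunteer arms and multiple-dose cancer-patient
    cohorts, as printed in the verification table."""
    return pd.read_csv(_OBS_DIR / "clinical_pk_summary.csv")


def load_ratio_table() -> pd.DataFrame:
    """Observed and simulated geometric-mean DDI / organ-impairment ratios
    (the 11 verification studies)."""
    return pd.read_csv(_OBS_DIR / "ddi_oi_ratios.csv")


def pk_table_pairs(metric: str) -> list[PredObsPair]:
    """Predicted/observed pairs for one metric from the PK summary table.

    ``metric``: ``cmax`` | ``auc`` | ``ctrough``.
    """
    df = load_pk_table()
    col_o, col_s = f"{metric}_obs", f"{metric}_sim"
    out = []
    for _, row in df.iterrows():
        if pd.notna(row[col_o]) and pd.notna(row[col_s]):
            out.append(PredObsPair(predicted=row[col_s], observed=row[col_o],
                                   label=row["label"], metric=metric))
    return out


def ratio_table_pairs(metric: str) -> list[PredObsPair]:
    """Predicted/observed ratio pairs (``auc`` or ``cmax``) from the DDI/OI
    verification table; main (post-adjustment) simulated values."""
    df = load_ratio_table()
    col_o, col_s = f"{metric}_ratio_obs", f"{metric}_ratio_sim"
    return [PredObsPair(predicted=row[col_s], observed=row[col_o],
                        label=row["label"], metric=f"{metric} ratio")
            for _, row in df.iterrows()]
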