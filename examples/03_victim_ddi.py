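"""Asciminib as the victim: strong CYP3A4 perpetrators and imatinib.

Paired mean-subject trials (each arm on identical physiology) reproduce
the verification interaction magnitudes; predictions are checked against
the observed clinical ratios with the Guest criteria.
"""
from ascipk import (Regimen, TrialDesign, calibrate, load_compound,
                    mean_subject, run_trial, trial_ratios, within_guest)

asciminib = load_compound("asciminib")
subject = mean_subject()
calibration = calibrate(asciminib, subject)

studies = [  # perpetrator, regimen, observed AUC ratio
    ("clarithromycin", Regimen(dose=500, interval="BID", n_days=8), 1.36),
    ("rifampicin", Regimen(dose=600, interval="QD", n_days=6), 0.851),
    ("imatinib", Regimen(dose=400, interval="QD", n_days=8), 2.08),
]
for name, perp_regimen, observed in studies:
    design = TrialDesign(
        victim=Regimen(dose=40, interval="single", start_day=5),
        perpetrator=perp_regimen, n_trials=1, n_subjects=1)
    df = run_trial(design, asciminib, load_compound(name),
                   calibration=calibration, subjects=[subject])
    aucr = trial_ratios(df, "auc_inf").geometric_mean_ratio
    guest = "inside" if within_guest(aucr, observed, 20.0) else "outside"
    print(f"{name:15s} predicted AUCR {aucr:5.2f}  observed {observed:5.2f}"
          f"  -> {guest} Guest limits (20% variability)")
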