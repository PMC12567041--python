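"""Asciminib as the perpetrator: sensitive CYP probe substrates.

Dynamic paired trials (probe alone vs probe + asciminib 40 mg BID) next
to the mechanistic-static net-effect screen computed from the simulated
steady-state concentrations.
"""
from ascipk import (PBPKSystem, Regimen, TrialDesign, calibrate,
                    load_compound, mean_subject, run_trial, trial_ratios)
from ascipk.staticddi import static_inputs_from_simulation, static_screen

asciminib = load_compound("asciminib")
subject = mean_subject()
calibration = calibrate(asciminib, subject)

probes = [("midazolam", 4.0, 5), ("swarfarin", 2.5, 8), ("repaglinide", 0.5, 3)]
for name, dose, days in probes:
    design = TrialDesign(
        victim=Regimen(dose=dose, interval="single", start_day=3),
        perpetrator=Regimen(dose=40, interval="BID", n_days=days),
        n_trials=1, n_subjects=1,
        washout_h=240.0 if name == "swarfarin" else 96.0)
    df = run_trial(design, load_compound(name), asciminib,
                   calibration=calibration, probe_mode=True,
                   subjects=[subject])
    print(f"{name:12s} dynamic AUCR "
          f"{trial_ratios(df, 'auc_inf').geometric_mean_ratio:5.2f}")

# static screen at 40 mg BID steady state (in-vitro constants)
system = PBPKSystem(asciminib, subject, calibration=calibration)
res = system.simulate({"asciminib": [(i*12.0, 40.0) for i in range(20)]}, 240.0)
mask = res.t >= 228.0
inputs = static_inputs_from_simulation(res.t[mask], res.plasma_conc()[mask],
                                       asciminib, 40.0, 12.0)
print("\nstatic net-effect screen (risk flags, in-vitro constants):")
print(static_screen(asciminib, inputs).to_string(index=False))
# The static screen overstates the dynamic interaction (worst-case Imax);
# both place asciminib 40 mg BID as a weak CYP3A4/2C9 inhibitor.
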