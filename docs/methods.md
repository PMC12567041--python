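# Methods

## Scope and intent

`ascipk` is a mechanistic simulator of asciminib disposition built around
one central phenomenon: saturable BCRP-mediated biliary efflux, which makes
clearance dose-dependent and couples every drug–drug-interaction (DDI) and
organ-impairment (OI) question to dose. The package contains the whole-body
model for asciminib itself, reduced stand-ins for co-administered drugs, a
synthetic virtual population, static DDI risk metrics, a virtual-trial
layer, and the standard predictive-performance statistics.

## Whole-body model

States are amounts (µmol); concentrations are µM internally and ng/mL at
the reporting boundary.

**Absorption.** A gut-lumen depot empties at ka = 1.3 h⁻¹ (lag 0.374 h);
the effective absorbed fraction is fa = 0.96 (the value that closes
F = fa·Fg·Fh = 0.73; a user-set fa of 1.00 with a predicted 0.96 are both
supported in configs, with 0.96 the default). Absorbed flux passes a
Q_gut-type enterocyte extraction, Fg = Q_gut/(Q_gut + fu_gut·CLu_int,gut)
with Q_gut = 5.3 L/h and fu_gut = 0.25; the gut intrinsic clearance
(CYP3A4) is set so baseline Fg = 0.83 and responds dynamically to
inhibition/induction. Surviving flux enters the liver extracellular space
(portal entry), so hepatic first pass is emergent rather than imposed.

**Distribution.** Eleven perfusion-limited tissues (lung in parallel in the
lumped-blood approximation) exchange with a single well-mixed blood pool.
The default distribution method ("uniform-tuned") assigns a uniform
plasma-referenced tissue partition coefficient of 0.28 and solves the
hepatocellular accumulation factor so whole-body Vss equals the 0.8 L/kg
target on the reference subject; the split between peripheral tissue and
hepatocellular binding was set once so the simulated single-dose profile
(Cmax ≈ 620 ng/mL, Tmax ≈ 1.9 h at 40 mg) matches the distribution phase of
the reference simulations. A tissue-composition predictor scaled by the
published Kp scalar (0.025) is implemented as an option, but for logP 3.9
it implies a Vss far above 0.8 L/kg, so the Vss-constrained uniform method
is the default; acceptance is defined on the Vss constraint, not the
method.

**Liver.** The liver is permeability-limited: extracellular (30% of liver
volume, blood-like) and intracellular (70%) spaces exchange by a passive
diffusion clearance CL_PD (0.06 mL/min/10⁶ cells, scaled by
hepatocellularity × liver mass ≈ 700 L/h on unbound concentrations).
Intracellular unbound concentration Cu = A/(V_IC·K_u), with K_u the solved
accumulation factor. Metabolism is Michaelis–Menten per enzyme
(v = Vmax·Cu/(Km,u + Cu)) plus a linear hydrolysis intrinsic clearance;
biliary efflux is J = Jmax·Cu/(Km + Cu) with the in-vitro-anchored
Km = 0.0071 µM, so the transporter runs near zero order at clinical
exposures and falls back to linear behaviour in the low-concentration tail.

**Renal.** Filtration-driven clearance scaled by subject GFR and unbound
fraction. The simulator uses the clearance implied by the fe ≈ 0.044
bookkeeping share (~0.23 L/h systemic) rather than the measured
1.8 mL/min = 0.108 L/h, because the measured value is inconsistent with the
fe share and the CL/F operating point taken together; the measured value
remains in the compound config as the datum it is, and the filtration-ratio
check (CLr/(fu·GFR) ≈ 0.56, i.e. net reabsorption) uses it directly.

## Retrograde parameterisation and calibration

Pathway fractions are bookkeeping on apparent oral clearance: the
hADME-derived UGT total (58.3%) is revised downward by the biliary fraction
defined through the with/without-transporter CL/F pair
(ft = 1 − 4.96/7.19 = 0.310), and the remainder is split across UGT1A3/4,
UGT2B7 and UGT2B17 by their in-vitro shares (24.2/47.9/27.9%), giving the
final fm values (6.6/13.1/7.6%). CYP, renal and hydrolysis shares pass
through unchanged.

The retrograde step inverts the well-stirred liver model to convert the
CL/F target plus fm values into whole-liver intrinsic clearances, and on to
per-pmol Vmax values through MPPGL × liver mass × abundance scaling.
Because the ODE model departs from the well-stirred idealisation
(permeability limitation, transporter saturation), two global scalars are
then calibrated numerically at the 20 mg BID operating point on the mean
subject: a metabolic scale such that simulated CL/F without the transporter
equals 4.96 L/h, and a BCRP activity scalar such that CL/F with the
transporter equals 7.19 L/h (equivalently ft = 0.31 at this dose). Both
solves converge in a handful of 15-day simulations; the scalars are then
held fixed for all doses, populations and scenarios.

Two definitions of "recovered pathway fraction" coexist and differ for a
saturable route: the CL/F-gap definition (used by the bookkeeping and by
the fixed-point check, because the targets were constructed that way) and
the raw elimination-flux share, which is larger for BCRP (removing the
transporter raises concentrations and the remaining routes compensate).
`SimulationResult.recovered_fractions` reports flux shares;
`recovered_pathway_fractions` reports the bookkeeping-consistent set, which
closes the retrograde→forward loop to within 0.3% absolute.

## Interaction layer

Reversible inhibition is competitive, CLint/(1 + Σ Iu/Ki,u) (implemented as
Km inflation for the Michaelis–Menten pathways and the transporter).
Induction uses the standard turnover model with kdeg = 0.0193 h⁻¹ (hepatic
CYP3A4), 0.0288 h⁻¹ (gut CYP3A4), 0.0183 h⁻¹ (CYP1A2). Time-dependent
inactivation terms exist in the static interface but are unity for
asciminib (no apparent in-vitro TDI).

Driver concentrations, a genuinely open design point, are fixed as:
asciminib's hepatic driver is its simulated intracellular unbound
concentration; reduced stand-ins use the unbound hepatic-inlet
approximation fu·(Cp + ka·A_lumen·F/Q_h), optionally multiplied by a
hepatic-uptake enrichment (imatinib, an OCT1 substrate, uses 5.6); the
enterocyte driver for all compounds is the unbound villous-blood value
fu·(Cp + ka·A_lumen/Q_villi) with Q_villi = 18 L/h. These conventions were
chosen once so that the interaction magnitudes driven by asciminib's own
measured constants (midazolam, S-warfarin, repaglinide) land on the
verification values without touching those constants.

**Stand-ins.** Perpetrators and probe substrates are one-compartment oral
models anchored to literature exposure. Printed interaction constants
(imatinib UGT1A3/1A4/2B17 IC50s, the vesicle-confirmed BCRP IC50 0.094 µM,
the rifampicin induction pairs) are carried verbatim. Where a reduced
stand-in lacks the structure behind an effective potency — clarithromycin's
time-dependent component, itraconazole's metabolite, the intracellular
inducer exposure of rifampicin — a single effective constant was fitted
top-down against that stand-in's own reference interaction study
(clarithromycin systemic Ki 0.14 µM with enterocyte-site Ki 10 µM;
itraconazole effective Ki 5 nM; rifampicin dynamic Indmax 6.0 against the
in-vivo-calibrated pair retained for the static module). This mirrors the
top-down refinements the underlying model programme itself applied.

**Static metrics.** The net-effect AUC ratio uses the guidance convention:
unbound hepatic inlet Imax and *total* enterocyte Igut = Fa·ka·Dose/Q_ent.
The basic screen runs on the in-vitro constants (CYP2C9 Ki,u 0.407 µM, not
the later top-down 0.03 µM), reproducing the published 1.9/1.3/1.1 flags;
RIS uses the in-vitro CYP3A4 induction pair with unbound steady-state Cmax,
and maps to a percent AUC reduction through a linear factor of 200 %/unit
(RIS 0.07 ↔ ~14%). The rifampicin in-vivo induction reference
(EC50 0.32 µM, Emax 14.94) is the pair implied by back-solving the
published calibrated asciminib values from the in-vitro pairs.

## Virtual population

Central physiology (organ volumes, flows, liver scalars) comes from
published reference-human tables; enzyme abundances and CVs from published
meta-analyses, all in a versioned data file (`data/population.yaml`). The
commercial population library behind the original analysis is proprietary,
so this population reproduces structure and means, not individuals: sex-
and weight-scaled volumes/flows (weight^0.75 for flows), log-normal
between-subject variability on abundances, transporter activity, liver
scalars, GFR and plasma-protein level. Child–Pugh classes scale functional
liver mass, CYP abundance, hepatic/portal flow, plasma protein and GFR with
documented cirrhosis constants; UGT activity is unchanged in CP-A/B, and
the UGT-modified severe class sets UGT1A4/UGT2B7 to 7.8/10.65 pmol/mg.
Renal impairment bins GFR (60–90 / 30–60 / <30 mL/min); severe-RI
simulations optionally apply the adjusted unbound fraction fu_p = 0.018.
The cancer base applies small documented modifiers (plasma protein ×1.08,
CYP ×0.93), keeping asciminib PK within 15% of the healthy base. What the
generator does **not** emulate: correlated covariate structure (e.g.
weight–abundance correlations), ethnic strata, paediatrics, disease
progression — so passing population tests demonstrates structural
plausibility and declared-mean fidelity, not individual-level realism.

## Trial layer and statistics

DDI designs are within-subject paired (both arms simulated on identical
physiology; the control arm simply omits perpetrator doses from the same
coupled system, so disabled interactions give ratios of exactly 1). OI
designs apply impairment modifiers to the sampled healthy subjects, giving
exactly demographics-matched controls. Non-compartmental metrics use dense
trapezoid AUCs with log-linear terminal extrapolation (omitted and flagged
when the terminal slope is not estimable); ratios are geometric means with
90% t-interval CIs on log ratios. Because pairing makes the ratio CIs very
tight (the reference simulated CIs are ±2%), verification checks run on the
mean reference subject; population runs exist for variability summaries and
use 10×10 designs by default, with smaller sizes in the examples.

Evaluation implements %PE, AFE/AAFE, GMFE, the twofold (|log10 R| < 0.301)
and 25% (< 0.097) bounds, and Guest limits with the bound factor
L = (δ + 2(R′−1))/R′ on the ≥1-oriented observed ratio, floored at 1.25 and
with δ = exp(1.116·CV/100) (δ = 1 at no variability, 1.25 at the
conventional 20%). The transcribed clinical verification tables ship as
CSVs and the printed summary statistics (AFE/AAFE 1.00/1.10 Cmax,
1.14/1.17 AUC, 1.13/1.29 Ctrough; GMFE 1.18/1.14) are recomputed from them
in the test suite.

## Numerical choices

LSODA with rtol 1e-6 and atol 1e-9 (amount units); doses are handled as
events between integration segments; dense output every 0.25 h. Mass
balance (body + bile + urine + gut-wall metabolism + flux-integrated
hepatic metabolism vs administered) closes to ~1e-4 of dose. Solver
step-control noise when co-compound states are added is below 1e-4
relative. All randomness flows through explicit numpy generators seeded per
trial; same seed, same tables.

## Known limitations

* **Enterohepatic recirculation sensitivity.** The EHC toggle returns a
  chosen fraction of biliary output to the absorbable lumen after a transit
  delay. With the biliary route calibrated to ~31% of low-dose clearance,
  full recirculation necessarily raises single-dose AUC by ~40% (and ~27%
  at 40 mg BID steady state) — a direct consequence of mass returned at
  F ≈ 0.73. A much smaller sensitivity would require most recycled drug to
  never reach the absorbable pool (bile-salt sequestration, distal-segment
  release), which this first-order absorption structure does not represent;
  the toggle should therefore be read as an upper bound on EHC impact.
* Reduced stand-ins have no mutual-PK feedback (a perpetrator's own
  exposure is unaffected by asciminib), which matters mainly for long
  co-administration at 200 mg BID.
* Itraconazole's hydroxy metabolite is folded into an effective parent Ki;
  metabolite kinetics (M30.5) are not tracked.
* Severe-RI exposure ratios are damped relative to the reference
  (AUCR ~1.2 vs ~1.4) because lowering the unbound fraction also
  desaturates the biliary pathway, which partially compensates; the Cmax
  ratio is reproduced.
* Fasted state only; no dissolution/precipitation model (supported by the
  low in-vitro precipitation, <20%, at clinical doses) and no food effect.
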