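# Versioned physiology constants for the synthetic virtual population.
#
# The commercial population library behind the original analysis is
# proprietary; the central values below are assembled from published
# reference-human tables (organ volumes and blood flows), liver scaling
# factors, and enzyme-abundance meta-analyses.  They are documented
# stand-ins: the population reproduces the *structure* (demographics,
# organ volumes/flows, hepatic enzyme/transporter abundance with
# log-normal between-subject variability, GFR strata, Child-Pugh
# modifiers), not any individual of the original library.
version: 1

reference:
  male:
    body_weight: 70.0        # kg
    cardiac_output: 390.0    # L/h blood
    blood_volume: 5.4        # L
    hematocrit: 0.45
    # organ volumes, L at reference body weight (scaled linearly with weight)
    tissue_volumes:
      lung: 0.5
      adipose: 14.0
      bone: 10.0
      brain: 1.45
      gut: 1.65
      heart: 0.33
      kidney: 0.31
      muscle: 29.0
      skin: 3.3
      spleen: 0.15
      rest: 4.1
    liver_volume: 1.65       # L
    liver_mass: 1650.0       # g
    # regional blood flows, L/h at reference cardiac output
    # (hepatic artery is listed separately; portal inflow = gut + spleen outflow)
    tissue_blood_flows:
      lung: 20.0
      adipose: 19.5
      bone: 19.5
      brain: 46.8
      gut: 46.8
      heart: 15.6
      kidney: 74.1
      muscle: 66.3
      skin: 19.5
      spleen: 7.8
      rest: 28.7
    hepatic_artery_flow: 25.4
  female:
    body_weight: 61.0
    cardiac_output: 351.0
    blood_volume: 4.6
    hematocrit: 0.40
    volume_scalars: {adipose: 1.45, muscle: 0.78, bone: 0.85}
    liver_scalar: 0.85

demographics:
  body_weight_cv: 15.0       # percent, log-normal
  default_age_range: [20, 55]
  default_female_proportion: 0.5

liver:
  mppgl: 39.8                # mg microsomal protein / g liver
  mppgl_cv: 25.0
  hepatocellularity: 118.0   # 10^6 cells / g liver
  hepatocellularity_cv: 20.0

gfr:
  healthy_mean: 110.0        # mL/min/1.73 m^2
  healthy_cv: 13.0

# hepatic enzyme abundances, pmol / mg microsomal protein, log-normal CVs in %.
# Healthy central values are documented defaults from published abundance
# meta-analyses (the original analysis does not print the values it used);
# UGT1A4 and UGT2B7 centrals match the baselines quoted for the severe-HI
# modification (52 and 71 pmol/mg).
enzyme_abundance:
  CYP3A4:  {mean: 137.0, cv: 41.0}
  CYP2C8:  {mean: 24.0,  cv: 50.0}
  CYP2C9:  {mean: 73.0,  cv: 45.0}
  CYP2C19: {mean: 14.0,  cv: 60.0}
  CYP1A2:  {mean: 52.0,  cv: 45.0}
  CYP2D6:  {mean: 8.0,   cv: 60.0}
  CYP2J2:  {mean: 1.2,   cv: 40.0}
  UGT1A1:  {mean: 60.0,  cv: 45.0}
  UGT1A3:  {mean: 26.0,  cv: 45.0}
  UGT1A4:  {mean: 52.0,  cv: 45.0}
  UGT2B7:  {mean: 71.0,  cv: 45.0}
  UGT2B17: {mean: 26.0,  cv: 70.0}

transporters:
  BCRP: {mean: 1.0, cv: 30.0}   # relative canalicular activity scalar

gut:
  cyp3a4_activity_cv: 40.0      # relative gut CYP3A4 activity, central 1.0

plasma_protein:
  scalar_cv: 6.0                # relative binding-protein level, central 1.0

populations:
  healthy:
    label: healthy north-European adult
  cancer:
    # cancer patients: slightly elevated alpha-1 acid glycoprotein and a
    # modest reduction in hepatic CYP activity; kept small, consistent with
    # the <15% PK difference between the two bases.
    plasma_protein_scalar: 1.08
    cyp_activity_scalar: 0.93

# Child-Pugh hepatic-impairment modifiers: documented constants from
# published cirrhosis physiology (functional liver mass, hepatic blood flow,
# CYP abundance, albumin).  UGT activity is unchanged in CP-A/CP-B; the
# ugt-modified CP-C variant applies the 85% UGT1A4/UGT2B7 reduction
# reported for severe cirrhosis.
impairment:
  CP-A:
    liver_mass: 0.90
    cyp3a4_abundance: 0.60
    other_cyp_abundance: 0.80
    ugt_abundance: 1.0
    hepatic_flow: 0.85
    plasma_protein: 0.90
    gfr: 0.90
  CP-B:
    liver_mass: 0.80
    cyp3a4_abundance: 0.45
    other_cyp_abundance: 0.65
    ugt_abundance: 1.0
    hepatic_flow: 0.70
    plasma_protein: 0.75
    gfr: 0.75
  CP-C:
    liver_mass: 0.67
    cyp3a4_abundance: 0.35
    other_cyp_abundance: 0.50
    ugt_abundance: 1.0
    hepatic_flow: 0.55
    plasma_protein: 0.60
    gfr: 0.60
  CP-C-ugt-modified:
    liver_mass: 0.67
    cyp3a4_abundance: 0.35
    other_cyp_abundance: 0.50
    ugt_abundance: 1.0
    ugt_overrides: {UGT1A4: 7.8, UGT2B7: 10.65}   # pmol/mg, 85% reduction
    hepatic_flow: 0.55
    plasma_protein: 0.60
    gfr: 0.60

renal_bins:
  RI-mild: [60.0, 90.0]      # mL/min
  RI-moderate: [30.0, 60.0]
  RI-severe: [15.0, 30.0]
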