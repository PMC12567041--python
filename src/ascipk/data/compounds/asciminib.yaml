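# Asciminib whole-body PBPK parameterisation.
# Sources: published physicochemistry/binding, in vitro enzyme and transporter
# kinetics, and top-down optimised absorption/distribution/transport constants.
name: asciminib
schema_version: 1
phys_chem:
  molecular_weight: 449.85
  logp: 3.9
  compound_class: monoprotic base
  pka: 4.0
binding:
  fu_plasma: 0.027
  fu_plasma_renal_impaired: 0.018
  blood_to_plasma: 0.80
absorption:
  # user-set fa is 1.00 with a predicted effective absorbed fraction of 0.96;
  # the effective value is what enters F = fa * Fg * Fh = 0.73 and is stored here.
  fa: 0.96
  fa_cv: 9.0
  ka: 1.3
  ka_cv: 9.0
  tlag: 0.374
  fu_gut: 0.25
  q_gut: 5.3
  q_gut_cv: 30.0
  # unbound gut CYP3A4 intrinsic clearance of the Q_gut model, set so that
  # baseline Fg = Q_gut / (Q_gut + fu_gut * gut_clint_u) = 0.83
  gut_clint_u: 4.342
  peff_human: 3.729
distribution:
  kp_scalar: 0.025
  vss_target: 0.8
  kp_method: uniform-tuned
enzymes:
  - {enzyme_id: CYP3A4,  vmax: 3.8,   km_u: 15.7,  fu_mic: 0.160,  fm_target: 0.351}
  - {enzyme_id: CYP2C8,  vmax: 0.136, km_u: 7.6,   fu_mic: 0.0829, fm_target: 0.005}
  - {enzyme_id: CYP2D6,  vmax: 0.736, km_u: 30.7,  fu_mic: 0.0680, fm_target: 0.002}
  - {enzyme_id: CYP2J2,  vmax: 0.355, km_u: 0.694, fu_mic: 0.0925, fm_target: 0.0076}
  - {enzyme_id: UGT1A3,  vmax: 1.73,  km_u: 12.9,  fu_mic: 0.0811, fm_target: 0.033}
  - {enzyme_id: UGT1A4,  vmax: 0.73,  km_u: 12.9,  fu_mic: 0.0811, fm_target: 0.033}
  - {enzyme_id: UGT2B7,  vmax: 2.04,  km_u: 12.7,  fu_mic: 0.0811, fm_target: 0.131}
  - {enzyme_id: UGT2B17, vmax: 17.7,  km_u: 9.41,  fu_mic: 0.0811, fm_target: 0.076}
transporters:
  - transporter_id: BCRP
    location: liver canalicular
    jmax: 0.2782
    km: 0.0070865
    cl_pd: 0.06
    ft_target_low_dose: 0.311
renal:
  cl_renal: 0.108   # 1.8 mL/min/1.73 m^2
  # final bookkeeping share of total clearance (urinary recovery of unchanged drug)
  fe_target: 0.044
additional_clearance:
  hlm_clint_u: 0.65
  pathway_label: hydrolysis
  fm_target: 0.0071
inhibition:
  - {target_id: CYP1A2,  ki_u: 10.4,  ic50_u: 20.8, conversion: half}
  - {target_id: CYP2A6,  ki_u: 43.6,  ic50_u: 87.1, conversion: half}
  - {target_id: CYP2B6,  ki_u: 2.62,  conversion: direct}
  - {target_id: CYP2C8,  ki_u: 0.466, conversion: direct}
  # top-down optimised from the S-warfarin interaction study
  - {target_id: CYP2C9,  ki_u: 0.03,  conversion: direct}
  # in vitro determined value, retained for the basic static screen
  - {target_id: CYP2C9_in_vitro, ki_u: 0.407, conversion: direct}
  - {target_id: CYP2C19, ki_u: 1.5,   ic50_u: 3.0,  conversion: half}
  - {target_id: CYP2D6,  ki_u: 8.5,   ic50_u: 17.0, conversion: half}
  - {target_id: CYP2E1,  ki_u: 37.5,  ic50_u: 75.0, conversion: half}
  - {target_id: CYP3A4,  ki_u: 0.348, conversion: direct}
  # Cheng-Prusoff with estradiol probe: Km = 16.8 µM, S = 10 µM
  - {target_id: UGT1A1,  ki_u: 0.35,  ic50_u: 0.56, conversion: substrate-corrected}
  - {target_id: UGT2B7,  ki_u: 7.28,  ic50_u: 7.28, conversion: direct}
  # transporter inhibition constants (total)
  - {target_id: P-gp,    ki_u: 21.7,  conversion: direct}
  - {target_id: BCRP,    ki_u: 0.088, conversion: direct}
  - {target_id: OATP1B1, ki_u: 2.46,  conversion: direct}
  - {target_id: OATP1B3, ki_u: 1.92,  conversion: direct}
  - {target_id: OAT1,    ki_u: 6.90,  conversion: direct}
  - {target_id: OAT3,    ki_u: 1.01,  conversion: direct}
  - {target_id: OCT1,    ki_u: 3.41,  conversion: direct}
  - {target_id: OCT2,    ki_u: 8.22,  conversion: direct}
  - {target_id: MATE1,   ki_u: 6.22,  conversion: direct}
  - {target_id: MATE2K,  ki_u: 2.36,  conversion: direct}
induction:
  - {target_id: CYP1A2, indc50: 0.59,  indmax: 4.5,  calibrated: false}
  # calibrated against the rifampicin positive control (in vitro pair: 2.7 µM, 5.4-fold)
  - {target_id: CYP3A4, indc50: 2.057, indmax: 1.53, calibrated: true}
  - {target_id: CYP3A4_in_vitro, indc50: 2.7, indmax: 5.4, calibrated: false}
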