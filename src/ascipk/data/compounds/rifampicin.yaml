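# Rifampicin stand-in: strong CYP3A4 inducer, 600 mg QD reference regimen.
# Induction parameters are the in-vivo-calibrated pair implied by the
# calibrator used for asciminib (EC50 0.32 uM, Emax 14.94 -> Indmax 15.94).
name: rifampicin
schema_version: 1
phys_chem: {molecular_weight: 822.94, logp: 2.7, compound_class: monoprotic acid, pka: 1.7}
binding: {fu_plasma: 0.15, blood_to_plasma: 0.9}
reduced_pk:
  ka: 1.15
  tlag: 0.5
  f_oral: 0.93
  v_central: 53.0
  cl: 12.0
  fu_plasma: 0.15
  fu_gut: 1.0
induction:
  # effective dynamic induction strength of the reduced stand-in, fitted
  # top-down to the reference induction study (a one-compartment stand-in
  # overstates the effective inducer exposure at the enzyme site); the
  # in-vitro pair (EC50 0.42 uM, Emax 124) and the in-vivo-calibrated pair
  # (0.32 uM, Emax 14.94) are carried as constants by the static module.
  - {target_id: CYP3A4, indc50: 0.32, indmax: 6.0, calibrated: true}
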