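# Clarithromycin stand-in: strong CYP3A4 inhibitor, 500 mg BID reference regimen.
# Reduced one-compartment PK anchored to literature steady-state exposure;
# the effective reversible CYP3A4 potency is calibrated top-down so the
# stand-in reproduces the clinical interaction magnitude of the reference
# study (clarithromycin combines reversible and time-dependent inhibition,
# which the reduced model folds into one effective constant).
name: clarithromycin
schema_version: 1
phys_chem: {molecular_weight: 747.95, logp: 3.16, compound_class: monoprotic base, pka: 8.99}
binding: {fu_plasma: 0.30, blood_to_plasma: 1.0}
reduced_pk:
  ka: 0.6
  f_oral: 0.55
  v_central: 200.0
  cl: 30.0
  fu_plasma: 0.30
  fu_gut: 1.0
  # enterocyte-site effective Ki (top-down, reference-study fit)
  ki_gut: {CYP3A4: 10.0}
inhibition:
  - {target_id: CYP3A4, ki_u: 0.14, conversion: direct}
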