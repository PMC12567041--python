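# Erythromycin stand-in: moderate CYP3A4 inhibitor, 500 mg QID; effective
# reversible potency folds in mechanism-based inactivation.
name: erythromycin
schema_version: 1
phys_chem: {molecular_weight: 733.93, logp: 3.06, compound_class: monoprotic base, pka: 8.88}
binding: {fu_plasma: 0.16, blood_to_plasma: 1.0}
reduced_pk:
  ka: 0.8
  f_oral: 0.35
  v_central: 55.0
  cl: 32.0
  fu_plasma: 0.16
  fu_gut: 1.0
inhibition:
  - {target_id: CYP3A4, ki_u: 0.18, conversion: direct}
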