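# Efavirenz stand-in: moderate CYP3A4 inducer, 600 mg QD.
name: efavirenz
schema_version: 1
phys_chem: {molecular_weight: 315.67, logp: 4.6, compound_class: neutral}
binding: {fu_plasma: 0.006, blood_to_plasma: 0.74}
reduced_pk:
  ka: 0.5
  f_oral: 0.45
  v_central: 250.0
  cl: 9.0
  fu_plasma: 0.006
  fu_gut: 1.0
induction:
  - {target_id: CYP3A4, indc50: 0.025, indmax: 7.5, calibrated: true}
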