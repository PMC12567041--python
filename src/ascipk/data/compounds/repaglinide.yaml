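# Repaglinide probe substrate: CYP2C8 (fm ~0.7) and CYP3A4 (fm ~0.3) victim,
# 0.5 mg oral single dose.
name: repaglinide
schema_version: 1
phys_chem: {molecular_weight: 452.59, logp: 3.97, compound_class: monoprotic acid, pka: 4.19}
binding: {fu_plasma: 0.015, blood_to_plasma: 0.62}
reduced_pk:
  ka: 2.0
  f_oral: 0.6
  v_central: 30.0
  cl: 33.0
  fu_plasma: 0.015
  fu_gut: 1.0
  fm: {CYP2C8: 0.7, CYP3A4: 0.29}
  fg_baseline: 0.95
  gut_fm_enzyme: CYP3A4
  q_gut: 18.0
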