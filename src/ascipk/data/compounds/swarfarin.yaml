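# S-warfarin probe substrate: sensitive CYP2C9 victim, 2.5 mg oral single dose.
name: swarfarin
schema_version: 1
phys_chem: {molecular_weight: 308.33, logp: 2.7, compound_class: monoprotic acid, pka: 5.0}
binding: {fu_plasma: 0.01, blood_to_plasma: 0.55}
reduced_pk:
  ka: 1.0
  f_oral: 0.95
  v_central: 10.0
  cl: 0.17
  fu_plasma: 0.01
  fu_gut: 1.0
  fm: {CYP2C9: 0.91}
  fg_baseline: 1.0
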