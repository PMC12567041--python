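# Caffeine probe substrate: sensitive CYP1A2 victim, 150 mg oral single dose.
name: caffeine
schema_version: 1
phys_chem: {molecular_weight: 194.19, logp: -0.07, compound_class: neutral}
binding: {fu_plasma: 0.65, blood_to_plasma: 1.0}
reduced_pk:
  ka: 3.0
  f_oral: 0.99
  v_central: 36.0
  cl: 5.5
  fu_plasma: 0.65
  fu_gut: 1.0
  fm: {CYP1A2: 0.9}
  fg_baseline: 1.0
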