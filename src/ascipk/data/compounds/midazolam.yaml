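# Midazolam probe substrate: sensitive CYP3A4 victim, 4 mg oral single dose.
# Baseline fraction escaping gut metabolism 0.62 (CYP3A4-mediated).
name: midazolam
schema_version: 1
phys_chem: {molecular_weight: 325.77, logp: 3.53, compound_class: monoprotic base, pka: 6.2}
binding: {fu_plasma: 0.032, blood_to_plasma: 0.66}
reduced_pk:
  ka: 2.0
  f_oral: 0.35
  v_central: 80.0
  cl: 27.0
  fu_plasma: 0.032
  fu_gut: 1.0
  fm: {CYP3A4: 0.94}
  fg_baseline: 0.62
  gut_fm_enzyme: CYP3A4
  q_gut: 14.0
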