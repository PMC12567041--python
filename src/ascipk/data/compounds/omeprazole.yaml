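# Omeprazole probe substrate: CYP2C19 victim (normal metabolisers), 20 mg oral.
name: omeprazole
schema_version: 1
phys_chem: {molecular_weight: 345.42, logp: 2.23, compound_class: monoprotic base, pka: 4.77}
binding: {fu_plasma: 0.043, blood_to_plasma: 0.59}
reduced_pk:
  ka: 1.5
  f_oral: 0.5
  v_central: 20.0
  cl: 30.0
  fu_plasma: 0.043
  fu_gut: 1.0
  fm: {CYP2C19: 0.87, CYP3A4: 0.1}
  fg_baseline: 1.0
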