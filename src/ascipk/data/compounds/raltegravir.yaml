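# Raltegravir probe substrate: UGT1A1 victim (fm ~0.9, 9% renal), 400 mg oral.
name: raltegravir
schema_version: 1
phys_chem: {molecular_weight: 444.42, logp: 0.58, compound_class: monoprotic acid, pka: 6.67}
binding: {fu_plasma: 0.17, blood_to_plasma: 0.6}
reduced_pk:
  ka: 0.8
  f_oral: 0.6
  v_central: 130.0
  cl: 60.0
  fu_plasma: 0.17
  fu_gut: 1.0
  fm: {UGT1A1: 0.9}
  fg_baseline: 1.0
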