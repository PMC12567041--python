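# Fluconazole stand-in: moderate CYP3A4 (and weak UGT2B7) inhibitor, 200 mg QD.
name: fluconazole
schema_version: 1
phys_chem: {molecular_weight: 306.27, logp: 0.4, compound_class: neutral}
binding: {fu_plasma: 0.89, blood_to_plasma: 1.0}
reduced_pk:
  ka: 1.1
  f_oral: 0.95
  v_central: 46.0
  cl: 1.1
  fu_plasma: 0.89
  fu_gut: 1.0
inhibition:
  - {target_id: CYP3A4, ki_u: 12.0,  conversion: direct}
  - {target_id: UGT2B7, ki_u: 250.0, conversion: direct}
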