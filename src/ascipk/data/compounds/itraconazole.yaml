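# Itraconazole stand-in (capsule, fasted): strong CYP3A4 inhibitor, 200 mg QD.
# The hydroxy-itraconazole metabolite is not modelled separately; its CYP3A4
# inhibition is folded into an effective parent Ki.
name: itraconazole
schema_version: 1
phys_chem: {molecular_weight: 705.63, logp: 5.66, compound_class: monoprotic base, pka: 3.7}
binding: {fu_plasma: 0.036, blood_to_plasma: 0.58}
reduced_pk:
  ka: 0.4
  tlag: 0.3
  f_oral: 0.55
  v_central: 700.0
  cl: 22.0
  fu_plasma: 0.036
  fu_gut: 1.0
  # negligible enterocyte contribution in the reduced stand-in
  ki_gut: {CYP3A4: 1000.0}
inhibition:
  - {target_id: CYP3A4, ki_u: 0.005, conversion: direct}
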