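# Imatinib stand-in: CYP3A4, UGT1A3/4, UGT2B17 and BCRP inhibitor, 400 mg QD.
# One-compartment PK anchored to literature steady-state exposure; UGT IC50s
# converted with the half rule; BCRP IC50 is the vesicle-confirmed value
# (10-fold below the nominal cellular assay estimate).  liver_enrichment
# reflects OCT1-mediated hepatocyte uptake.
name: imatinib
schema_version: 1
phys_chem: {molecular_weight: 493.60, logp: 3.0, compound_class: monoprotic base, pka: 8.27}
binding: {fu_plasma: 0.05, blood_to_plasma: 1.09}
reduced_pk:
  ka: 0.61
  f_oral: 0.98
  v_central: 295.0
  cl: 10.0
  fu_plasma: 0.05
  fu_gut: 1.0
  liver_enrichment: 5.6
inhibition:
  - {target_id: CYP3A4,  ki_u: 1.0,   conversion: direct}
  - {target_id: UGT1A3,  ki_u: 10.0,  ic50_u: 20.0, conversion: half}
  - {target_id: UGT1A4,  ki_u: 7.5,   ic50_u: 15.0, conversion: half}
  - {target_id: UGT2B17, ki_u: 0.035, ic50_u: 0.07, conversion: half}
  - {target_id: BCRP,    ki_u: 0.094, conversion: direct}
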