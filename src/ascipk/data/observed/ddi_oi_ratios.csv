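label,kind,cmax_ratio_obs,cmax_ratio_sim,cmax_rpredobs,auc_ratio_obs,auc_ratio_sim,auc_rpredobs,cmax_ratio_sim_initial,auc_ratio_sim_initial
clarithromycin,victim_ddi,1.19,1.05,0.882,1.36,1.32,0.971,,
itraconazole,victim_ddi,1.04,1.05,1.01,1.04,1.24,1.19,,
rifampicin,victim_ddi,1.09,0.838,0.769,0.851,0.566,0.665,,
imatinib,victim_ddi,1.59,1.15,0.723,2.08,1.99,0.957,1.14,1.56
midazolam,perpetrator_ddi,1.11,1.18,1.06,1.28,1.23,0.961,,
swarfarin,perpetrator_ddi,1.08,1.03,0.954,1.41,1.40,0.993,,
repaglinide,perpetrator_ddi,1.14,1.07,0.939,1.08,1.10,1.02,,
mild_hi,organ_impairment,1.26,0.966,0.767,1.22,1.11,0.910,,
moderate_hi,organ_impairment,0.983,0.908,0.924,1.03,1.32,1.28,,
severe_hi,organ_impairment,1.29,0.776,0.602,1.66,1.28,0.771,,
severe_ri,organ_impairment,1.08,1.14,1.06,1.56,1.44,0.923,0.818,0.970
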