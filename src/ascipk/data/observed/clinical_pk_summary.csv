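label,group,regimen,day,cmax_obs,cmax_sim,auc_obs,auc_sim,ctrough_obs,ctrough_sim,tmax_obs_median,tmax_sim_median
clarithromycin_ddi_control,healthy,40 mg single,1,567,625,6040,5490,,,2.02,1.20
rifampicin_ddi_control,healthy,40 mg single,1,595,627,5870,5520,,,2.00,1.20
itraconazole_ddi_control,healthy,40 mg single,1,594,623,6000,5436,,,2.01,1.20
fasted_control,healthy,40 mg single,1,589,619,6040,5299,,,2.01,1.25
hepatic_impairment_control,healthy,40 mg single,1,584,659,5000,6306,,,2.00,1.22
renal_impairment_control,healthy,40 mg single,1,584,696,5720,6904,,,2.03,1.26
fih_20mg_bid_d1,cancer,20 mg BID,1,249,305,1053,1529,,,2.07,1.20
fih_20mg_bid_d15,cancer,20 mg BID,15,339,445,2515,3216,114,149,2.98,1.14
fih_20mg_bid_d28,cancer,20 mg BID,28,537,445,2977,3216,128,149,2.03,1.15
fih_40mg_bid_d1,cancer,40 mg BID,1,653,618,2695,3187,,,2.10,1.24
fih_40mg_bid_d15,cancer,40 mg BID,15,806,980,5519,7545,309,385,2.11,1.18
fih_40mg_bid_d28,cancer,40 mg BID,28,873,980,5777,7544,308,384,2.01,1.15
fih_80mg_bid_d1,cancer,80 mg BID,1,1365,1206,5628,6308,,,2.88,1.24
fih_80mg_bid_d15,cancer,80 mg BID,15,2127,1939,11971,15100,1087,780,2.13,1.18
fih_80mg_bid_d28,cancer,80 mg BID,28,2165,1939,14327,15096,1020,779,2.02,1.19
fih_160mg_bid_d1,cancer,160 mg BID,1,2923,2508,13706,13360,,,2.10,1.24
fih_160mg_bid_d15,cancer,160 mg BID,15,4327,4373,30577,35506,2193,1962,2.17,1.18
fih_160mg_bid_d28,cancer,160 mg BID,28,4809,4373,32768,35495,2559,1960,2.02,1.17
fih_200mg_bid_d1,cancer,200 mg BID,1,3646,3275,16788,17646,,,2.03,1.28
fih_200mg_bid_d15,cancer,200 mg BID,15,5700,6052,45641,50649,3191,2910,2.10,1.22
fih_200mg_bid_d28,cancer,200 mg BID,28,6069,6050,40639,50622,3137,2906,2.00,1.19
fih_80mg_qd_d1,cancer,80 mg QD,1,1253,1301,5780,6874,,,2.06,1.22
fih_80mg_qd_d15,cancer,80 mg QD,15,1595,1587,14702,17541,227,303,2.15,1.18
fih_80mg_qd_d28,cancer,80 mg QD,28,1826,1587,15633,17544,208,303,2.00,1.19
fih_120mg_qd_d1,cancer,120 mg QD,1,2199,1942,9543,10333,,,2.04,1.22
fih_120mg_qd_d15,cancer,120 mg QD,15,2405,2396,21924,26948,342,481,2.03,1.22
fih_120mg_qd_d28,cancer,120 mg QD,28,2547,2396,21829,26956,332,480,2.00,1.22
fih_200mg_qd_d1,cancer,200 mg QD,1,3963,3271,17234,17482,,,2.00,1.22
fih_200mg_qd_d15,cancer,200 mg QD,15,4228,4152,40612,48302,787,928,2.05,1.18
fih_200mg_qd_d28,cancer,200 mg QD,28,4502,4152,39144,48309,523,927,2.02,1.19
phase3_40mg_bid_d15,cancer,40 mg BID,15,1010,1030,6070,8062,324,422,1.97,1.16
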