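name,index,mw,log_p,pka,log_d,solubility_mg_ml,ref_ph,papp_cm_s,rbp_rat,rbp_human,fup_rat,fup_human,cl_rat,vss_rat,dose_base,enzyme,km_um,vmax_nm_min_nm
3'-methoxydadizein,1,284.27,2.676,8.510,2.640,0.0205,6.32,0.220e-5,0.915,0.807,8.403,7.394,2.786,54.730,0.062,CYP1A2,44.408,9.308
8-O-methylretusin,2,298.30,2.805,8.830,2.850,0.0108,6.60,2.480e-5,0.875,0.777,11.816,7.07,1.906,5.860,0.11,CYP1A2,5.409,8.998
daidzin,3,416.38,0.541,9.650,0.560,0.720,6.40,0.400e-5,1.044,0.744,39.933,17.891,4.669,17.36,0.71,none,,
isolariciresinol,4,360.41,1.591,9.370,2.020,0.201,6.17,0.220e-5,0.830,0.787,31.535,16.139,7.152,17.03,1.31,CYP2C9,16.423,7.152
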