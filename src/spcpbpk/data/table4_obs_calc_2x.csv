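compound,metric,calc,val,fe_printed
3'-methoxydadizein,cmax,0.0068,0.0072,1.06
3'-methoxydadizein,tmax,0.64,0.55,1.16
3'-methoxydadizein,auc_t,0.0183,0.0191,1.04
3'-methoxydadizein,auc_inf,0.0193,0.0200,1.04
8-O-methylretusin,cmax,0.0257,0.0253,1.02
8-O-methylretusin,tmax,0.20,0.25,1.25
8-O-methylretusin,auc_t,0.0288,0.0153,1.88
8-O-methylretusin,auc_inf,0.0292,0.0155,1.88
daidzin,cmax,0.0334,0.0272,1.23
daidzin,tmax,0.32,0.25,1.28
daidzin,auc_t,0.0393,0.0355,1.11
daidzin,auc_inf,0.0400,0.0359,1.11
isolariciresinol,cmax,0.0494,0.0417,1.16
isolariciresinol,tmax,0.32,0.30,1.20
isolariciresinol,auc_t,0.0791,0.0557,1.42
isolariciresinol,auc_inf,0.0805,0.0593,1.36
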