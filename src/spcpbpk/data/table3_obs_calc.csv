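compound,metric,obs,calc,fe_printed
3'-methoxydadizein,cmax,0.0039,0.0034,1.15
3'-methoxydadizein,tmax,0.42,0.64,1.52
3'-methoxydadizein,auc_t,0.0084,0.0092,1.10
3'-methoxydadizein,auc_inf,0.0090,0.0097,1.08
8-O-methylretusin,cmax,0.0136,0.0130,1.05
8-O-methylretusin,tmax,0.25,0.20,1.25
8-O-methylretusin,auc_t,0.0097,0.0144,1.48
8-O-methylretusin,auc_inf,0.0115,0.0146,1.27
daidzin,cmax,0.0151,0.0167,1.11
daidzin,tmax,0.21,0.32,1.52
daidzin,auc_t,0.0284,0.0196,1.45
daidzin,auc_inf,0.0305,0.0200,1.52
isolariciresinol,cmax,0.0262,0.0247,1.06
isolariciresinol,tmax,0.31,0.32,1.03
isolariciresinol,auc_t,0.0347,0.0395,1.14
isolariciresinol,auc_inf,0.0383,0.0403,1.05
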