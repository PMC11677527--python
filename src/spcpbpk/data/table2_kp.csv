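tissue,3'-methoxydadizein,8-O-methylretusin,daidzin,isolariciresinol
Lung,0.45,2.42,0.48,1.25
Adipose,0.07,6.84,0.15,2.23
Muscle,0.39,1.19,0.36,0.70
Liver,0.37,2.05,0.37,1.04
Spleen,0.39,1.14,0.39,0.69
Heart,0.40,1.67,0.43,0.92
Brain,1.60,4.73,0.44,2.11
Kidney,0.73,1.92,0.42,1.02
Skin,1.09,2.72,0.47,1.35
ReproOrg,0.41,1.93,0.43,1.02
RedMarrow,0.33,2.51,0.31,1.17
YellowMarrow,0.07,6.84,0.15,2.23
RestOfBody,0.42,1.16,0.40,0.71
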