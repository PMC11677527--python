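# Rat reference physiology (0.25 kg). Volumes/flows follow standard
# fractional compilations (Brown et al.-style), scaled linearly to body
# weight and normalized so that the perfused-tissue flows sum exactly to
# cardiac output (hepatic artery + portal flow folded into liver flow).
# Users may substitute their own values; the loader re-checks invariants.
species: rat
body_weight_kg: 0.25
cardiac_output_l_h: 6.6
e_to_p: 1.0                 # erythrocyte:plasma concentration ratio (Vss eq.)
lumen_volume_l: 0.006       # small-intestinal fluid available for dissolution
intestinal_radius_cm: 0.18
volumes_l:
  lung: 0.00125
  liver: 0.0085
  kidney: 0.001825
  heart: 0.000825
  muscle: 0.101
  spleen: 0.0005
  brain: 0.001425
  gi: 0.00675
  rest: 0.1097
  artery: 0.00617
  venous: 0.01233
  plasma: 0.0100
  erythrocyte: 0.0085
flows_l_h:
  lung: 6.6            # = cardiac output
  liver: 1.2078        # includes portal (gi) inflow
  gi: 0.8646
  kidney: 0.9306
  heart: 0.3234
  muscle: 1.8348
  spleen: 0.066
  brain: 0.132
  rest: 2.1054
# Tissue volumes used only in the steady-state distribution-volume sum
# (13 tissues matching the partition-coefficient table).
vss_volumes_l:
  Lung: 0.00125
  Adipose: 0.019
  Muscle: 0.101
  Liver: 0.0085
  Spleen: 0.0005
  Heart: 0.000825
  Brain: 0.001425
  Kidney: 0.001825
  Skin: 0.0475
  ReproOrg: 0.0025
  RedMarrow: 0.00188
  YellowMarrow: 0.0025
  RestOfBody: 0.0423
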