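# Human reference physiology (70 kg adult male). Same conventions as
# rat.yaml: fractional reference values, flows normalized to sum exactly to
# cardiac output with portal flow folded into liver flow.
species: human
body_weight_kg: 70.0
cardiac_output_l_h: 390.0
e_to_p: 1.0
lumen_volume_l: 0.25
intestinal_radius_cm: 1.25
volumes_l:
  lung: 0.532
  liver: 1.82
  kidney: 0.308
  heart: 0.329
  muscle: 28.0
  spleen: 0.182
  brain: 1.40
  gi: 1.19
  rest: 30.71
  artery: 1.843
  venous: 3.687
  plasma: 3.00
  erythrocyte: 2.53
flows_l_h:
  lung: 390.0
  liver: 88.53
  gi: 70.59
  kidney: 68.25
  heart: 15.6
  muscle: 74.49
  spleen: 3.003
  brain: 44.46
  rest: 95.667
vss_volumes_l:
  Lung: 0.532
  Adipose: 10.0
  Muscle: 28.0
  Liver: 1.82
  Spleen: 0.182
  Heart: 0.329
  Brain: 1.40
  Kidney: 0.308
  Skin: 2.6
  ReproOrg: 0.035
  RedMarrow: 1.05
  YellowMarrow: 1.4
  RestOfBody: 16.814
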