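# Case 2 — pericarditis-like ECG hiding a proximal LAD occlusion.
# A woman in her early forties with substernal pain radiating to both
# axillae. Diffuse ST elevation without reciprocal depression was read as
# pericarditis; terminal QRS distortion in V3 invoked the comprehensive
# occlusion-sign tier. Angiography: totally occluded mid-LAD.
#
# The published counterfactual (same 1.4% anchor, pleuritic pain ~0.5, then
# the negative comprehensive-ECG LR ~0.23 for "no OMI signs") is exercised
# through the counterfactual operation, not stored as checkpoints.
id: 2
title: "Pericarditis-like ECG"
citation: "Dr. Smith's ECG Blog: you diagnose pericarditis at your peril"
age: 42
sex: female
evidence:
  - label: "Radiation to both arms"
    feature: {id: radiation_both_arms, present: true}
  - label: "Typical ischemic chest pain"
    feature: {id: typical_chest_pain, present: true}
    checkpoint: {percent: 6.6, decimals: 1, tolerance: 0.1}
  - label: "Occlusion-specific ECG signs (comprehensive read)"
    test: {id: ecg_omi_comprehensive, result: positive}
    lr: 14  # published chaining value; Sn/Sp-derived is 13.946
    checkpoint: {percent: 50, decimals: 0, tolerance: 1.0}
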