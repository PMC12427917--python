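# Case 5 — false-positive occlusion finding (South African Flag pattern).
# A 58-year-old man with stabbing left-sided pain radiating to the shoulder.
# The field ECG suggested a mid-anterior occlusion pattern meeting
# millimetric criteria; a normal bedside echo and two low-normal troponins
# later pulled the probability back down, and angiography found no culprit.
#
# Autonomic symptoms (nausea, diaphoresis) contribute LR ~ 1 in the
# published chain and are omitted as neutral. The echo/troponin
# down-weighting is narrative-only (no LR published) and is excluded from
# checkpoints; the Queen-of-Hearts-negative branch is available through the
# counterfactual operation using the catalog's AI-classifier entry.
id: 5
title: "False-positive occlusion pattern (South African Flag)"
citation: "Dr. Smith's ECG Blog: cath lab occupied — which patient should go?"
age: 58
sex: male
evidence:
  - label: "Male sex"
    male_sex: true
    checkpoint: {percent: 9, decimals: 0, tolerance: 1.0}
  - label: "Typical anginal character"
    feature: {id: typical_chest_pain, present: true}
  - label: "Radiation to the left arm"
    feature: {id: radiation_left_arm, present: true}
    checkpoint: {percent: 19.6, decimals: 1, tolerance: 0.1}
  - label: "Millimetric ST-elevation pattern"
    test: {id: ecg_ste_only, result: positive}
    lr: 12.5
    checkpoint: {percent: 75, decimals: 0, tolerance: 1.0}
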