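# Case 1 — teenager with classic anterior ST elevation.
# A 17-year-old male with 1-2 h of typical chest pain; the ECG showed 4-6 mm
# of ST elevation in V2-V6 with hyperacute anterior T waves, initially read
# as benign early repolarization. Angiography 5 days later: total thrombotic
# LAD occlusion.
#
# The published chain applies the youngest (18-34) anchor to a 17-year-old;
# the engine does the same with a logged warning. The published male-sex
# checkpoint is 0.21% where exact odds arithmetic gives 0.2209% (rounds to
# 0.22%); the checkpoint keeps the published figure with the one-decimal
# tolerance class rather than silently correcting it.
id: 1
title: "Teenager with classic anterior ST elevation"
citation: "Dr. Smith's ECG Blog: a teenager with chest pain and rising troponin"
age: 17
sex: male
evidence:
  - label: "Male sex"
    male_sex: true
    checkpoint: {percent: 0.21, decimals: 2, tolerance: 0.1}
  - label: "Typical chest pain"
    feature: {id: typical_chest_pain, present: true}
  - label: "Pain developed within 24 h"
    feature: {id: pain_change_24h, present: true}
    checkpoint: {percent: 0.8, decimals: 1, tolerance: 0.1}
  - label: "Anterior ST elevation (millimetric criteria)"
    test: {id: ecg_ste_only, result: positive}
    lr: 12.5  # published chaining value; Sn/Sp-derived is 12.457
    checkpoint: {percent: 9.2, decimals: 1, tolerance: 0.1}
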