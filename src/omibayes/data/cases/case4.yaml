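# Case 4 — intermediate pre-test probability, precordial swirl pattern.
# A previously healthy 40-year-old woman with sudden retro-sternal pressure.
# The ECG showed 1-2 mm ST elevation in V1-V2, a hyperacute T wave in V2 and
# reciprocal depression in V4-V6 (precordial swirl). A single negative
# presentation troponin briefly pushed the probability down before serial
# values ruled in necrosis; intravascular ultrasound found a ruptured
# proximal-LAD plaque extending into the distal left main.
#
# The published chain uses the unrounded comprehensive-tier LR+ 13.95
# (= 0.781/0.056) here, where Case 2 used the rounded 14 — both are kept as
# published.
id: 4
title: "Intermediate pre-test probability, precordial swirl"
citation: "Dr. Smith's ECG Blog: the dye don't lie — except when it does"
age: 40
sex: female
evidence:
  - label: "Typical ischemic chest pain"
    feature: {id: typical_chest_pain, present: true}
    checkpoint: {percent: 2.6, decimals: 1, tolerance: 0.1}
  - label: "Precordial swirl (comprehensive OMI read)"
    test: {id: ecg_omi_comprehensive, result: positive}
    lr: 13.95
    checkpoint: {percent: 27, decimals: 0, tolerance: 1.0}
  - label: "Negative initial hs-troponin"
    test: {id: troponin_initial, result: negative}
    checkpoint: {percent: 9.4, decimals: 1, tolerance: 0.1}
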