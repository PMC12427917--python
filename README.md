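# omibayes

Sequential Bayesian diagnosis of **occlusion myocardial infarction (OMI)**
for emergency-department chest-pain presentations.

Millimetric ST-elevation (STEMI) criteria miss roughly half of
angiographically proven acute coronary occlusions. Recasting the question
as *"how probable is an occluded artery?"* turns ECG interpretation from a
binary rule into a transparent probability calculation: start from an age-
and sex-specific baseline prevalence (the *anchor*), and update it with a
likelihood ratio (LR) for each clinical finding, biomarker and ECG pattern.
`omibayes` implements that calculation as a reusable, fully audited engine
for emergency physicians, educators and methodologists who want to
inspect, teach or stress-test this style of diagnostic reasoning.

## The model

Evidence acts multiplicatively on the odds scale:

```
odds = P / (1 − P)
posterior odds = prior odds × LR₁ × LR₂ × ⋯ × LRₖ
P = odds / (1 + odds)
```

For a test with sensitivity Sn and specificity Sp,

```
LR+ = Sn / (1 − Sp)      LR− = (1 − Sn) / Sp      DOR = LR+ / LR−
```

The chain is exact Bayes when findings are conditionally independent given
disease status; correlated findings double-count evidence, and the
`cohort` module measures how badly (calibration slope on the logit scale).
The Fagan nomogram is the same arithmetic drawn as a straight line across
three aligned scales; the `nomogram` module renders it as deterministic
SVG, with the geometry verified against the arithmetic to 1e−9.

What ships:

- `core` — probability/odds conversions, LR chaining with a full audit
  trace, Monte-Carlo propagation of LR confidence intervals;
- `catalog` — the editable evidence base: anchor prevalences per age band
  (with their derivation pipeline), pre-ECG clinical LRs, and test entries
  (two ECG reading tiers, an AI ECG classifier, troponin strategies);
- `decision` — action tiers (catheterization >10%, fibrinolysis >75%) and
  the classical Pauker–Kassirer test/treatment threshold expressions;
- `nomogram` — Fagan nomogram layout and SVG export, single update or
  chained ladder;
- `cases` — five published case walkthroughs as replayable fixtures, every
  printed probability checkpoint audited, plus counterfactual branches;
- `cohort` — synthetic-cohort simulation, calibration reports, and
  threshold operating-characteristic sweeps;
- `cli` — the `omibayes` command (`assess`, `replay`, `simulate`,
  `nomogram`, `catalog-validate`).

## Worked example

A 58-year-old man with typical anginal pain radiating to the left arm,
whose ECG meets millimetric ST-elevation criteria:

```python
from omibayes import (anchor_probability, chain_update,
                      EvidenceItem, LikelihoodRatio, recommend)

p0 = anchor_probability(58, "male")          # 0.0904  (9.0%)
trace = chain_update(p0, [
    EvidenceItem("typical pain",            LikelihoodRatio(1.9)),
    EvidenceItem("left-arm radiation",      LikelihoodRatio(1.3)),
    EvidenceItem("millimetric STE pattern", LikelihoodRatio(12.5)),
])
for s in trace.steps:
    print(f"{s.label:25s} xLR {s.lr_value:5.2f} -> {s.post*100:5.1f}%")
print(recommend(trace.posterior.p).value)
```

prints

```
typical pain              xLR  1.90 ->  15.9%
left-arm radiation        xLR  1.30 ->  19.7%
millimetric STE pattern   xLR 12.50 ->  75.4%
activate_cath_and_lysis_eligible
```

The 55–64 male anchor is 9.0%; symptoms lift it to 19.7% pre-ECG, the
ST-elevation pattern (LR+ 12.5) to 75.4% — past both the 10%
catheterization trigger and the 75% fibrinolysis-eligibility mark. (In the
published case this patient turned out to be a false positive: a normal
echo and flat troponins later pulled the probability back down, which is
the point — the estimate stays updatable in both directions.)

The same case from the command line, replaying the published walkthrough
with its printed intermediate rounding:

```
$ omibayes replay 1
Case 1: Teenager with classic anterior ST elevation
anchor (female, age 17): 0.17%
step                                                LR   post %
Male sex                                           1.3     0.22
Typical chest pain                                 1.9     0.42
Pain developed within 24 h                           2     0.80
Anterior ST elevation (millimetric criteria)      12.5     9.20
checkpoints:
  Male sex                                 published   0.21% computed   0.22% (tol 0.1) pass
  Pain developed within 24 h               published   0.80% computed   0.80% (tol 0.1) pass
  Anterior ST elevation (millimetric crite published   9.20% computed   9.20% (tol 0.1) pass
```

A 0.8% pre-test probability becomes 9.2% after one strongly specific ECG
finding — a probability no adolescent chest-pain encounter should shrug
off, and the reason the engine keeps the whole audit trail.

## Caveat

This package is a didactic instrument for probabilistic reasoning, not a
medical device. Its anchors, LRs and thresholds are published estimates
that users are expected to audit — and, where their setting differs,
replace (the catalog is a plain YAML file for exactly that reason).
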