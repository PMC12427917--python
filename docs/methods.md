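# Methods

## Model

The engine treats diagnosis of occlusion myocardial infarction (OMI) as
sequential Bayesian updating on the odds scale. A prior probability
`P₀` — the *anchor*, the baseline OMI prevalence for the patient's age
band and sex among ED chest-pain presentations — is converted to odds
`O₀ = P₀/(1−P₀)` and multiplied by one likelihood ratio per finding:

```
Oₖ = O₀ · LR₁ · LR₂ · ⋯ · LRₖ ,   Pₖ = Oₖ/(1+Oₖ)
```

The chain is exact Bayes if and only if findings are conditionally
independent given disease status. That assumption is wrong for colinear
findings (two ECG signs of the same lesion, say), and the package treats
it as a *measurable* assumption rather than a hidden one: the cohort
simulator quantifies the mis-calibration it produces (below).

Probabilities are fractions in the open interval (0, 1) everywhere inside
the package; percent appears only at I/O boundaries (reports serialize
probabilities as percent with one decimal). Degenerate priors 0 and 1 are
rejected, not absorbed: an endpoint probability can never be updated
again, and the framework's premise is that the estimate stays refreshable
— negative evidence pushes the probability down, never to zero.

## The evidence catalog

All numbers live in one editable YAML document (`data/catalog.yaml`);
package code contains no clinical constants. Three sections:

**Anchors.** Each age band stores the STEMI ED-visit rate per 10,000
adults and the derived figures. The derivation pipeline is part of the
API (`derive_anchor_table`): chest pain is ~5% of ED encounters, so
STEMI prevalence among chest-pain visits = rate/10,000/0.05; occlusions
missed by millimetric criteria add ~70%, so P(OMI) = 1.7 × STEMI
prevalence; the open-ended ≥85 band is capped at 25% (rounded down for
frail, multi-morbid populations). Anchors are tabulated for women; male
odds are 1.3× at any age (applied on the odds scale, so the male anchor
stays a valid probability at every prevalence). Band membership is
closed-open on years: [18, 35), [35, 45), …, [85, ∞). Ages under 18 map
to the youngest band with a logged warning — the published material does
the same for a 17-year-old, and refusing would be less useful than
flagging.

One published figure does not reproduce: the 35–44 prevalence is printed
as 0.82% where the pipeline yields 0.80%. The catalog stores the printed
value with an explicit `derivation_whitelisted` flag; `catalog-validate`
reports the row as a whitelisted discrepancy rather than passing or
fixing it silently. Validation tolerance is half of the last printed
digit of each stored figure (0.005 pp for two-decimal entries, 0.05 pp
for one-decimal), which is what "agrees at printed precision" means.

**Clinical features.** Pre-ECG LR+/LR− pairs for chest-pain descriptors
and history, with 95% CIs. Source rows published only as a *span* of
study estimates (no pooled point) store the span midpoint as the point
value, flagged `is_range` — the midpoint convention is this catalog's
choice, stated, not the source's.

**Tests.** ECG reading tiers (millimetric ST-elevation only: Sn 43.6%,
Sp 96.5%; comprehensive occlusion-sign spectrum: Sn 78.1%, Sp 94.4%), an
AI ECG classifier (Sn 80%, Sp 98% at its standard operating point), and
troponin strategies. Entries carry Sn/Sp, stated LRs, or both. Stated LRs
take lookup precedence because sources print rounded LRs that their own
rounded Sn/Sp do not exactly regenerate (e.g. LR+ 12.5 vs derived
12.457); chains should match the published arithmetic. Boundary entries
are flagged, not crashed on: Sp = 1 gives an infinite LR+, Sn = 1 gives
LR− = 0 — honest summaries of a study with no false positives
(negatives), but unusable as multiplicative evidence, so looking up that
branch raises with an explanation.

## Rounding policies

Published bedside chains round intermediate probabilities before reusing
them; exact chaining gives visibly different numbers (0.8% → 9.2% with
the rounded intermediate, 9.5% without). Two policies:

- `full_precision` — no intermediate rounding; posterior equals a single
  update by the LR product (order-invariant, collapsible, both tested at
  1e−12).
- `printed_checkpoint` — at steps that carry a printed checkpoint, the
  output probability is rounded on the percent scale (decimal `ROUND_HALF_UP`,
  to the per-step decimal count declared in the fixture) before feeding
  the next step. A step may additionally *force-carry* the published
  value where the published sequence continued from a graphically
  read-off figure (one case continues from "17%" where recomputation
  gives 16.4%); the audit still records what the arithmetic gives.

Checkpoint tolerances are ±0.1 percentage points for one-decimal
checkpoints and ±1.0 for integer ones, reflecting nomogram read-off and
reporting precision. Across all five shipped cases the two policies end
within 2 percentage points of each other (tested), which bounds the
practical cost of bedside rounding; near a decision threshold that gap
can still matter, which is why both policies are exposed.

## Decision thresholds

Pragmatic tiers: posterior **>10%** supports catheterization-lab
activation (angiography both confirms and treats, at low procedural
risk); **>75%** additionally supports fibrinolysis when angiography is
unavailable (treatment before anatomic confirmation, non-trivial
hemorrhagic risk). Comparisons are strictly greater-than; a posterior
exactly at a threshold stays in the lower tier (the published material
does not say which way the boundary goes; strict `>` is this package's
documented choice). Thresholds are parameters, not constants — systems
with longer transport times or higher bleeding risk should slide them.

The classical Pauker–Kassirer expressions are implemented so users can
check the pragmatic targets against a utility-based derivation:

```
no-test treatment threshold = Rrx/(Rrx+Brx)
testing threshold           = ((1−Sp)·Rrx + Rt) / ((1−Sp)·Rrx + Sn·Brx)
test-treatment threshold    = (Sp·Rrx − Rt) / (Sp·Rrx + (1−Sn)·Brx)
```

(Brx net benefit of treating diseased, Rrx net harm of treating
non-diseased, Rt test risk, all on one utility scale; results clamped to
[0,1]; a negative test-treatment numerator flags the test as never worth
its risk.) With Rt = 0 both expressions reduce to the threshold-odds
identity *prior odds × LR = Rrx/Brx*, which is how the frozen test values
were derived independently (e.g. Brx:Rrx = 9:1 with the comprehensive ECG
tier gives 0.79% and 32.4%).

## Nomogram geometry

Left axis y = −log10(prior odds), right axis y = +log10(posterior odds),
middle axis y = log10(LR)/2, axes at abscissae 0, 1, 2. The half-span
middle axis is forced by collinearity: the line through the left and
middle anchors reaches the right axis at `2·y_mid − y_left =
log10(prior odds · LR)`. `NomogramLayout.read_off()` performs exactly
that extrapolation, and the property suite checks geometric read-off
against the arithmetic at 1e−9 over a random grid — the drawing *is* the
calculation. Axis ranges are 0.1–99.9% and LR 0.001–1000; out-of-range
inputs clip with a warning. SVG output contains no timestamps and uses
fixed float formatting, so identical inputs are byte-identical.

## Interval propagation

Catalog LRs carry 95% intervals; `propagate_interval` gives a Monte-Carlo
posterior interval by drawing each LR independently on the log scale,
Normal(log value, sd) with sd = (log hi − log lo)/(2·1.96), chaining on
the odds scale, and taking the 2.5th/97.5th percentiles. Independence
across items is an approximation, the same one the chain itself makes.
Items lacking an interval are an explicit error (named per item); the
published material prints CIs but never propagates them, so this is
engine plumbing, clearly separated from replayed numbers.

## Cohort simulation

`simulate_cohort` generates patients under the framework's own generative
model: disease ~ Bernoulli(prevalence) (or per-patient anchors drawn from
the age/sex table — equal band weights and a 50/50 sex split, an
arbitrary documented default, since no target case-mix is published);
finding *j* positive with probability Snⱼ in the diseased and 1−Spⱼ in
the non-diseased. Findings specified only by LRs are converted: given
LR+ and a marginal positivity rate *q* in the non-diseased, Sp = 1−q and
Sn = LR+·q (solved values logged); given an LR+/LR− pair, Sp =
(LR+−1)/(LR+−LR−), Sn = LR+(1−Sp).

Correlation is induced by a one-factor Gaussian copula: per patient a
shared standard-normal factor plus independent noise, `z = √ρ·z₀ +
√(1−ρ)·ε`, thresholded at each finding's marginal quantile, identical ρ
in both disease classes. This is deliberately the simplest mechanism
that demonstrates the failure mode; it is not a model of real symptom
dependence.

`calibration_report` bins predicted posteriors (equal-width partition of
[0,1]; empty bins reported with count 0) and fits the logistic regression
of observed disease on logit(posterior) — calibration slope 1 and
intercept 0 mean the predicted probabilities are frequencies. Under ρ = 0
the chained posterior is the exact conditional probability (verified
against exhaustive enumeration at 1e−12 for ≤3 findings), so the slope CI
covers 1 at n = 100,000. With duplicated findings at ρ = 0.5 the slope
drops to ≈0.48 and its CI excludes 1 — serial multiplication
over-counts correlated evidence and pushes posteriors toward the
extremes. `policy_sweep` evaluates activation rate, sensitivity for
occlusion and false-activation fraction over a threshold grid on one
simulated cohort; both rates are non-increasing in the threshold.

What the simulator does *not* emulate: real case-mix and spectrum
effects, verification bias, time-varying findings, inter-rater ECG
variability, or continuous biomarker kinetics. Passing calibration tests
shows the engine is internally coherent under its stated assumptions —
not that the catalog's LRs are correct for any particular ED.

## Case replay

The five published walkthroughs ship as YAML fixtures (demographics,
ordered evidence, printed checkpoints with per-step decimals and
tolerances, narrative citation). The chain always starts from the female
anchor, with male sex as an explicit first evidence step, so the sex
adjustment appears in the audit trail exactly as in the published
arithmetic. Where the published chain grouped several features under one
multiplier ("typical pain radiating posteriorly" as a single 1.9), the
fixture mirrors the grouping rather than substituting per-feature catalog
rows; where it chained a rounded LR (12.5, 14) or an unrounded one
(13.95) the fixture keeps the value as published, with the catalog entry
attached for provenance. `counterfactual` replays a case with labeled
steps replaced, dropped, or re-pointed at catalog entries (the
pericarditis-style branch of the second case; the AI-classifier-negative
branch of the fifth), leaving fixtures untouched.

## Numerical choices

- Percent-scale rounding uses `decimal.Decimal` with `ROUND_HALF_UP` on
  the shortest-repr of the float — bedside convention, avoiding banker's
  rounding surprises at e.g. 55.5 → 56.
- `apply_lr(p, 1.0)` returns `p` unchanged (exact neutrality, no
  round-trip noise).
- Anchor sanity constraints are enforced at catalog load: contiguous
  ordered bands, non-decreasing anchors with age, unbounded top band;
  unknown keys anywhere in catalog/fixture/config files are schema
  errors.
- Seeds: every stochastic routine (interval propagation, cohort
  simulation) takes an explicit seed and is reproducible bit-for-bit.
- Problem sizes: calibration experiments use n = 100,000 patients
  (sub-second, vectorized); interval propagation defaults to 10,000
  draws, with 100,000 used where a tight bracket is asserted.

## Known limitations

- Serial LR multiplication ignores finding correlation; the simulator
  demonstrates the consequence but the engine deliberately offers no
  multivariable correction.
- The catalog's LRs pool STEMI and non-occlusive ACS sources and carry
  the biases of their parent studies; sign-specific ECG accuracies
  (swirl, terminal QRS distortion, …) do not exist in isolation yet and
  are approximated by the pooled comprehensive tier.
- Calibration claims are internal-coherence claims, not external
  validity; no real patient data enters this package.
- Threshold recommendations are didactic tier labels; clinical use of
  these numbers is out of scope by design.
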