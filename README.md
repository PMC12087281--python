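# mcedscreen

Modeling the benefit of cancer-signal-origin (CSO) prediction for multi-cancer
early detection (MCED) screening.

A blood-based MCED test detects a shared cancer signal across many cancer types
and, on a positive result, predicts the anatomic origin of the signal so that
the diagnostic workup can start with the usual site-directed pathway. This
package models the chain from population incidence to clinical payoff for that
prediction: who screens positive, which origin they are assigned, how likely
each CSO-directed workup is to find a cancer, and how many diagnostic tests are
spent per life saved — for researchers in cancer-screening policy and test
developers who need these quantities by population stratum.

## The model

For a stratum (sex × 5-year age band × smoking status) with stage-resolved
incidence `I(c, s)` per 100,000 person-years:

- **Interception.** Each cancer progresses I→II→III→IV with exponential stage
  sojourns (mean dwell time `d_s`), becomes blood-detectable at an onset stage
  and stays detectable. Screens recur every `T` years at uniform phase. The
  per-stage capture probability is `q_s = (d_s/T)(1 − e^(−T/d_s))`, and a
  cancer clinically diagnosed at stage `s_clin` with shedding onset `b` is
  intercepted at the first captured stage `j ∈ [b, s_clin]`, yielding the
  detected-stage × counterfactual-clinical-stage distribution. Onset weights
  are increments of the isotonic envelope of the per-stage sensitivities.
  False positives are `fp_rate × (cohort − detected)` — a single rate that does
  not accumulate over CSO categories.
- **CSO assignment.** The validation confusion matrix is smoothed with the
  training-prior frequencies as pseudo-counts,
  `p(o|c) = (n(c,o) + α·π(o)) / (Σ n(c,·) + α)`, and all positives — true
  positives of every class and false positives — are spread over predicted
  CSOs.
- **Diagnostic chain.** With `A` true positives in a predicted-CSO pool, `M` of
  them matching the prediction, and `F` false positives:
  `PPV_any = A/(A+F)`, `PPV_first = M/(A+F)`,
  `PPV_remaining = (A−M)/((A−M)+F)`.
- **Outcomes.** Each intercepted cancer contributes
  `Δ = s5(c, s_det) − s5(c, s_clin)` expected 5-year survivors; tests per life
  saved are pool sizes divided by summed `Δ`, benchmarked against 240
  diagnostic mammograms per life saved.
- **Uncertainty and strategies.** Conjugate posterior draws
  (Beta for rates, Dirichlet for confusion rows) propagate input uncertainty;
  directed-then-general, directed-only, and general-only workup strategies are
  compared on tests, lives and residual risk.

Every closed-form interception number is cross-checked against an exact
phase-type computation (matrix exponentials) and an individual-level
Monte-Carlo cohort simulator; synthetic inputs with known ground truth stand in
for registry and validation-study data.

## Worked example

```bash
python examples/run_screening_model.py
```

prints, for 65-69-year-old females screened annually (synthetic inputs,
seed 1):

```
                n_pool  ppv_any  ppv_first  ppv_remaining  tests_per_life_first  included
predicted_cso
lung           152.968    0.369      0.351          0.028                16.729      True
breast         206.351    0.546      0.543          0.007                 8.949      True
prostate        21.400    0.276      0.000          0.276                     -     False
colorectal     117.485    0.091      0.026          0.067               251.445      True
thyroid         95.102    0.025      0.000          0.025                     -     False
myeloid         96.093    0.022      0.000          0.022            155238.961     False
```

Reading the lung row: 153 of 100,000 screened enter a lung-directed workup;
36.9% of them have some cancer, 35.1% have a cancer the lung-directed workup
will find, and after lung cancer is ruled out 2.8% of the remainder still
harbor another cancer; about 17 lung-directed tests are spent per life saved —
far below the 240-mammogram benchmark. `prostate` is excluded in a female
stratum (no detectable prostate cancers), `thyroid` because the test sheds no
signal for it, and `myeloid` because the classifier never predicts it
correctly; their pools are mostly false positives, which is exactly what the
flags communicate. Other examples cover the confusion smoothing, the
three-way interception cross-check, uncertainty intervals with strategy
comparison, and age/smoking strata.

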