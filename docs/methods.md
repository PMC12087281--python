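# Methods

## Scope

`mcedscreen` estimates the conditional clinical benefit of the cancer-signal-
origin (CSO) prediction attached to a positive multi-cancer early detection
(MCED) screen: per predicted CSO and population stratum, it computes the pool
of individuals entering a CSO-directed workup, the three-tier positive
predictive values of the diagnostic chain, the expected lives saved from stage
shift, diagnostic tests per life saved, posterior uncertainty intervals, and
comparisons of workup strategies. All computations are expectation-level
(expected counts per cohort), with an individual-level simulator used for
validation only.

## Natural-history and interception model

Each incident cancer of class `c` clinically diagnosed at stage `s_clin`
traverses stages I→II→III→IV with independent exponential sojourns of mean
`d(c, s)` years; the time from entering `s_clin` to clinical diagnosis is
exponential with the same mean `d(c, s_clin)`. Detectability follows a monotone
shedding trajectory: onset at some stage `b`, detectable ever after. Onset
weights are the increments of the isotonic (least-squares,
pool-adjacent-violators) envelope of the raw per-stage sensitivities; the
envelope also defines the detectable fraction `ŝ_s` used wherever a standing
pool is screened once. Isotonic projection is used because raw stage-wise
sensitivity estimates from a finite study can dip non-monotonically from
sampling noise while the trajectory family is monotone by assumption.

Screens recur every `T` years (default 1) with uniform random phase. For one
exponential stage the capture probability is exactly
`q = E[min(sojourn, T)]/T = (d/T)(1 − e^(−T/d))`. Across multiple stages the
closed-form pipeline multiplies per-stage captures as independent events:
`P(intercept at j | onset b) = q_j ∏_{k=b}^{j−1}(1 − q_k)`. This independence
is an approximation — the same phased screen stream covers all stages — chosen
for closed-form tractability. The package therefore also carries the exact
computation (`oracle.py`): the wait from shedding onset to the next screen is
U(0, T) independent of the sojourns, so exact interception probabilities are
integrals of hypoexponential survival functions, evaluated in closed form via
`α'Q⁻¹(e^{QT} − I)1` on the bidiagonal sojourn generator. On the default
synthetic configuration the approximation understates detections by about 2%
relative (the product form double-counts the chance that the single stream
misses successive short stages); the acceptance suite bounds the per-class
relative gap at 10% for the default scenario and 20% for the adversarial
long-dwell scenario, and reports it. The Monte-Carlo cohort simulator draws a
single phased stream per person, so analytic-vs-simulated discrepancies beyond
sampling noise isolate exactly this approximation.

Two screening rounds are modeled. The steady-state *incidence round* covers
`T` years of incident cancers. The first-screen *prevalence round* screens the
standing preclinical pool, which is length-biased: cancers destined for
clinical diagnosis at `s_clin` contribute `incidence × d(c, j)` pool members
currently in each stage `j ≤ s_clin`, each detected with probability `ŝ_j` at
the current stage. Conservation in the prevalence round is over the pool, not
annual incidence.

Unstaged incidence is carried through detection (late-stage detectability
`ŝ_IV` and dwell `d_IV`) so it counts toward pools and PPVs, but it is never
stage-shifted and contributes zero lives saved. The false-positive total is
`fp_rate × (cohort − detected persons)`; the difference from
`fp_rate × cohort` is below 1% at realistic yields.

## CSO assignment

Predicted-CSO distributions are smoothed with the reference prior `π` (the
clinical-CSO frequencies among signal-detected training cases) as
pseudo-counts: `p(o|c) = (n(c,o) + α·π(o)) / (Σ_o' n(c,o') + α)` for true
positives, and the analogous form over the observed FP predictions for false
positives. The default α = 1 total pseudo-count per row is deliberately weak —
well-observed rows barely move, an unobserved row falls back to the prior, and
every probability is strictly positive. Sensitivity to α can be explored
through the uncertainty module, which reuses `counts + α·π` as the Dirichlet
concentration. Classes with no expected CSO ("other") use a dedicated
confusion row when the data provide one, else the reference prior itself.
Predictions are not sex-restricted — a male can receive a breast CSO —
while clinical incidence upstream is.

## Diagnostic chain and outcomes

Both diagnostic steps are assumed 100% sensitive for their target (the
site-directed step for the matching cancer class, the general step for any
cancer) and 0% otherwise, so all matched true positives resolve at step one,
cross-talk cancers resolve at the general step, and false positives persist
until the general step rules them out. PPV tiers follow directly from the pool
composition (`A`, `M`, `F`); empty pools yield flagged nulls, never zeros.
The 7% workup threshold is compared inclusively (a pool exactly at the line
passes).

"Lives saved" is the expected increment in 5-year survivors,
`Δ = s5(c, s_det) − s5(c, s_clin)` per intercepted cancer — no discounting, no
life-years. Negative gaps (noisy survival inputs) clamp to zero with a
warning. Tests are counted as one directed test per pool member and one
general test per member not resolved at step one; ratios with zero lives in
the denominator are flagged undefined rather than infinite. Summaries
(median, range) run over *modelable* CSOs only: a CSO is excluded when no
mapped class is detectable, its confusion diagonal is zero, or stage-resolved
survival is missing; the inclusion set accompanies every summary.

Two mortality variants:

- **Competing risks**: every contribution is multiplied by the stratum's
  5-year all-cause survival, applied per stratum (the natural level for an
  age-band factor); this never increases lives saved.
- **Shedding hazard**: ctDNA-detectable cancers are assumed to carry an h-fold
  hazard relative to non-shedding cancers while the observed mixture survival
  is preserved: `s_det = s^{hk}`, `s_non = s^k`, with `k` solved by bracketed
  root finding from
  `f·s^{hk} + (1−f)·s^k = s`, where `f = ŝ_s` is the stage's detectable
  fraction. Screen-detected cancers then use `s_det` at both the detected and
  counterfactual stages. The direction of this variant is *not* fixed: the
  detectable subgroup's survival drop is larger where mixture survival is
  lower (pushing the early/late gap wider) and where the detectable fraction
  is smaller (pushing it narrower, since `f` rises with stage). On the default
  synthetic configuration the aggregate effect is a reduction, but per-CSO
  values can move either way; the invariant the package guarantees and tests
  is that the variant changes only the outcome layer — PPVs are untouched.

## Uncertainty propagation

Sensitivities and the FP rate get Jeffreys-prior Beta posteriors from their
(success, total) evidence counts; confusion rows and the FP-CSO vector get
Dirichlet posteriors with the α-scaled reference prior. Draws stream through
the full pipeline; 2.5%/97.5% draw quantiles form the intervals. Variance is
attributed by resampling one input block at a time with the others held at
point estimates, and normalizing block variances — a deliberately cheap
one-at-a-time decomposition, not Sobol indices, sufficient to rank drivers.
Which block dominates depends on the evidence profile: with the synthetic
default of only ~5 observed FP CSO predictions, the CSO-assignment block (which
owns the FP-CSO Dirichlet) can dominate PPV variance over the FP rate itself.
Draw failures skip the draw and are counted, never silently imputed.

## Synthetic data and validation strategy

The generator fabricates every input with known ground truth: class totals
spanning three orders of magnitude, stage distributions and survivals drawn
within realistic envelopes, stage-increasing sensitivities averaging near one
half with a 0.5% FP rate and an ~89% confusion diagonal under the `realistic`
difficulty, one class that never sheds (thyroid-like), one CSO never predicted
correctly (myeloid-like), sex-restricted classes, and smoking-sensitive
classes (lung-like RRs of 1/5/15 for never/former/current against prevalence
weights 0.55/0.30/0.15). Dwell defaults are 2/1/1/0.5 years for stages I-IV
(half under `fast_aggressive`) — placeholder magnitudes on the natural scale
of screening intervals, not calibrated values. Emitted files round-trip
exactly through the production readers (17-significant-digit CSV, round-trip
float parsing).

What passing tests show — and do not show — about real data: the synthetic
conditions exercise the pipeline's structure (conservation, exclusion flags,
cross-talk, sex restriction, orders-of-magnitude pool imbalance), so green
tests certify the calculus, not the epidemiology. Real registry incidence has
calendar trends, age-standardization questions and stage-migration artifacts;
real validation studies have correlated sensitivity estimates and
non-exchangeable FP behavior. None of those are emulated, and quantitative
outputs on synthetic inputs carry no clinical meaning.

Validation is three-way: closed form vs exact phase-type (deterministic gap,
bounded and reported), exact vs Monte-Carlo cohort (within 3 standard errors
at 200,000 persons), and file round-trip vs stored ground truth (equality at
1e-9). Problem sizes in the shipped tests — 8 classes, 6 CSOs, 200,000
simulated persons, 200 posterior draws — were chosen as the smallest sizes at
which every Monte-Carlo band is meaningfully narrow.

## Numerical choices

- Isotonic projection via least squares (PAV); ties and violators are averaged.
- Hazard-split root: `brentq` on a bracket grown geometrically from [1e-12, 1];
  degenerate inputs (mixture survival 0 or 1, fraction outside (0,1), h < 1)
  are rejected or fall back to the mixture in the lives-saved wrapper.
- Phase-type integrals via `scipy.linalg.expm` on ≤4×4 generators.
- Quantities that would divide by zero (PPVs of empty pools, tests-per-life
  with zero lives, break-even with equal general-test counts) are NaN with
  flags, and reports omit the corresponding bars.
- Determinism: every stochastic component takes a `numpy` Generator seed;
  pipeline bundles are byte-identical under identical manifests.

## Limitations

- Downstream diagnostic tests are perfectly sensitive; imperfect workups would
  lower yields but not the orderings the tests assert.
- No overdiagnosis, no harm from unnecessary tests or incidental findings, no
  health-economic costing beyond the abstract expense ratio.
- One incidence round and one prevalence round; no multi-round cohort dynamics
  or repeat-test confirmation strategies.
- The independence approximation in the closed form is quantified, not
  eliminated; users needing exact numbers can call the phase-type route, which
  is a drop-in replacement at ~10x the cost.
- Expected-count arithmetic throughout: integer-person effects (a pool of 0.3
  individuals) are meaningful only at the cohort-expectation level.
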