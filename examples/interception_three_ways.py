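"""One interception computation, three routes: closed form, exact, simulated.

The closed-form model multiplies per-stage capture probabilities as if screens
landed independently in each stage; the exact route integrates the phase-type
sojourn distribution against the uniform screen phase; the Monte-Carlo route
simulates 200,000 individual screening histories.  Their agreement (and the
small, documented independent-capture gap) is the package's core validity
check.
"""

import pandas as pd

import mcedscreen as m

truth = m.generate_synthetic_inputs(seed=1)
rates = m.stratum_incidence(truth.incidence, truth.truth_stratum)
dwell = truth.dwell_scenarios["default"]

analytic = m.incidence_round_interception(rates, truth.perf, dwell, truth.cfg)
exact = m.exact_incidence_round_interception(rates, truth.perf, dwell, truth.cfg)
sim = m.simulate_screening_cohort(truth, 200_000, seed=2)

scale = 200_000 / truth.cfg.cohort_size
table = pd.concat(
    [
        analytic.detected_by_class().rename("closed_form"),
        exact.detected_by_class().rename("exact"),
        (sim.interception.detected_by_class() / scale).rename("simulated"),
    ],
    axis=1,
).fillna(0.0)
print("Screen-detected cancers per 100,000 screened, by class:")
print(table.round(2))
print()
gap = m.approximation_gap(analytic, exact)
print(f"Largest relative independent-capture gap: {gap['rel_gap'].abs().max():.2%}")
print(
    "The exact and simulated columns agree within Monte-Carlo noise; the "
    "closed form sits within a ~2% documented approximation of both."
)
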