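"""How PPV varies across age bands and smoking strata.

Cancer incidence rises with age while the false-positive count stays fixed, so
every PPV rises with age; smoking multiplies the incidence of smoking-related
cancers, moving the lung-CSO PPV most.
"""

import pandas as pd

import mcedscreen as m

truth = m.generate_synthetic_inputs(seed=1)


def ppv_any(stratum):
    inc = truth.incidence
    if stratum.smoking != "any":
        inc = m.apply_smoking_adjustment(inc, truth.smoking, stratum.smoking)
    rates = m.stratum_incidence(inc, stratum)
    res = m.incidence_round_interception(
        rates, truth.perf, truth.dwell_scenarios["default"], truth.cfg
    )
    strat = m.stratify_positives(res, truth.cso_model, truth.registry)
    return m.chain_ppvs(strat, truth.registry).table["ppv_any"]


ages = pd.DataFrame(
    {f"{lo}-{lo+4}": ppv_any(m.StratumSpec("female", lo, lo + 5)) for lo in (55, 65, 75)}
)
print("PPV-any by age band (females, any smoking):")
print(ages.round(3))
print()
smoking = pd.DataFrame(
    {s: ppv_any(m.StratumSpec("female", 65, 70, s)) for s in ("never", "any", "current")}
)
print("PPV-any by smoking status (females 65-69):")
print(smoking.round(3))
print()
print(
    "Every column is the chance that an individual entering that CSO-directed "
    "workup truly has cancer. PPVs climb with age (more cancers, same false "
    f"positives) and the lung row moves from {smoking.loc['lung', 'never']:.0%} "
    f"in never-smokers to {smoking.loc['lung', 'current']:.0%} in current smokers."
)
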