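"""End-to-end run: synthetic inputs -> pipeline -> per-CSO metric table.

Generates a synthetic study-input set (incidence, test performance, CSO
confusion counts, survival), runs the full model for 65-69-year-old females,
and prints the per-predicted-CSO diagnostic-chain metrics.
"""

import tempfile
from pathlib import Path

import mcedscreen as m

tmp = Path(tempfile.mkdtemp())
truth = m.generate_synthetic_inputs(seed=1, out_dir=tmp / "inputs")
paths = {p.stem: p for p in (tmp / "inputs").iterdir()}

cfg = m.RunConfig(
    registry_path=str(paths["registry"]),
    incidence_path=str(paths["incidence"]),
    performance_path=str(paths["performance"]),
    dwell_path=str(paths["dwell"]),
    confusion_path=str(paths["confusion"]),
    fp_counts_path=str(paths["fp_counts"]),
    prior_path=str(paths["prior"]),
    survival_path=str(paths["survival"]),
    os_path=str(paths["os"]),
    out_dir=str(tmp / "out"),
    strata=[m.StratumSpec("female", 65, 70)],
    fp_rate=truth.perf.fp_rate,
)
bundle = m.run_pipeline(cfg)
m.write_report(bundle)

table = bundle.per_stratum["female 65-69 any"]
cols = ["n_pool", "ppv_any", "ppv_first", "ppv_remaining",
        "tests_per_life_first", "included"]
print(table[cols].round(3).to_string(na_rep="-"))
print()
print(bundle.summary.round(3).to_string(index=False))
print()
print(
    "Each row is one predicted cancer signal origin: n_pool individuals enter "
    "its workup per 100,000 screened, ppv_any of them truly have cancer, and "
    "tests_per_life_first site-directed tests are spent per life saved "
    "(mammography benchmark: 240). Excluded rows lack the evidence to model."
)
print(f"Full table bundle and figures written to {tmp / 'out'}")
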