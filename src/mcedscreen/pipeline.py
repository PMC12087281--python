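"""End-to-end orchestration: configuration, per-stratum runs, result bundles.

A run walks each requested population stratum through incidence lookup (with
smoking adjustment where requested), interception, CSO stratification, chain
PPVs, outcomes, and optionally the strategy comparison, writing long-format
metric tables, a cross-stratum summary and a machine-readable manifest (hashed
inputs, seed, package version) so a bundle can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chain import apply_flags, chain_ppvs, modelable_cso_flags, threshold_report
from .cso import load_confusion, build_cso_model, stratify_positives
from .incidence import (
    ANY_SMOKING,
    StratumSpec,
    apply_smoking_adjustment,
    load_incidence,
    load_smoking_risks,
    stratum_incidence,
)
from .interception import (
    INCIDENCE_ROUND,
    PREVALENCE_ROUND,
    ScreeningConfig,
    incidence_round_interception,
    load_dwell,
    load_performance,
    prevalence_round_interception,
)
from .outcomes import load_survival, stage_shift_lives_saved, tests_per_life
from .strategy import expense_breakeven_ratio, strategy_compare
from .synthetic import load_registry

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "n_pool", "n_any", "n_match", "fp",
    "ppv_any", "ppv_first", "ppv_remaining",
    "lives_first", "lives_post",
    "tests_first", "tests_post",
    "tests_per_life_first", "tests_per_life_post",
    "vs_benchmark_first", "vs_benchmark_post",
    "detectable", "cso_predictable", "survival_available", "included",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs: input paths, strata, knobs, output dir."""

    registry_path: str
    incidence_path: str
    performance_path: str
    dwell_path: str
    confusion_path: str
    fp_counts_path: str
    prior_path: str
    survival_path: str
    out_dir: str
    strata: list[StratumSpec]
    os_path: str | None = None
    smoking_rr_path: str | None = None
    smoking_weights_path: str | None = None
    fp_rate: float = 0.005
    alpha: float = 1.0
    threshold: float = 0.07
    benchmark: float = 240.0
    round: str = INCIDENCE_ROUND
    dwell_scenario: str = "default"
    screen_interval: float = 1.0
    cohort_size: float = 100_000.0
    run_strategy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be inside (0, 1)")
        if self.benchmark <= 0:
            raise ValueError("benchmark must be positive")
        for name in ("registry_path", "incidence_path", "performance_path",
                     "dwell_path", "confusion_path", "fp_counts_path",
                     "prior_path", "survival_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        strata = [StratumSpec(**s) for s in raw.pop("strata")]
        return cls(strata=strata, **raw)


@dataclass
class RunBundle:
    """In-memory result of one pipeline run; mirrored on disk in ``out_dir``."""

    out_dir: Path
    per_stratum: dict[str, pd.DataFrame] = field(default_factory=dict)
    strategy_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    failures: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute the full model for every requested stratum and write the bundle.

    A module error inside one stratum aborts that stratum with a logged cause;
    remaining strata still run.  The returned bundle's ``failures`` map is empty
    on a fully successful run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    registry = load_registry(config.registry_path)
    incidence = load_incidence(config.incidence_path, registry)
    perf = load_performance(config.performance_path, fp_rate=config.fp_rate)
    dwell = load_dwell(config.dwell_path, config.dwell_scenario)
    confusion = load_confusion(config.confusion_path, config.fp_counts_path, config.prior_path)
    survival = load_survival(config.survival_path, config.os_path)
    model = build_cso_model(confusion, config.alpha)
    smoking = None
    if config.smoking_rr_path and config.smoking_weights_path:
        smoking = load_smoking_risks(config.smoking_rr_path, config.smoking_weights_path)

    scfg = ScreeningConfig(
        screen_interval=config.screen_interval,
        cohort_size=config.cohort_size,
        round=config.round,
    )
    intercept = (
        incidence_round_interception
        if config.round == INCIDENCE_ROUND
        else prevalence_round_interception
    )

    bundle = RunBundle(out_dir=out)
    for stratum in config.strata:
        try:
            inc = incidence
            if stratum.smoking != ANY_SMOKING:
                if smoking is None:
                    raise ValueError(
                        "smoking-specific stratum requested without RR/weight tables"
                    )
                inc = apply_smoking_adjustment(incidence, smoking, stratum.smoking)
            rates = stratum_incidence(inc, stratum)
            interception = intercept(rates, perf, dwell, scfg)
            strat = stratify_positives(interception, model, registry)
            metrics = apply_flags(
                chain_ppvs(strat, registry),
                modelable_cso_flags(interception, confusion, survival, registry),
            )
            lives = stage_shift_lives_saved(strat, survival, registry)
            outcomes = tests_per_life(lives, metrics, benchmark=config.benchmark)
            table = metrics.table.join(
                outcomes.table[[c for c in outcomes.table.columns
                                if c not in metrics.table.columns]]
            )
            table = table[[c for c in METRIC_COLUMNS if c in table.columns]]
            table = table.join(threshold_report(metrics, config.threshold))
            bundle.per_stratum[stratum.label] = table
            if config.run_strategy:
                comp = strategy_compare(strat, metrics, outcomes)
                stra = comp.table.copy()
                stra["expense_breakeven"] = expense_breakeven_ratio(comp)
                bundle.strategy_tables[stratum.label] = stra
            pool_total = strat.total_positives()
            logger.info(
                "stratum %s: %.1f detected, %.1f FPs, stratified-pool residual %.2e",
                stratum.label,
                interception.total_detected(),
                interception.fp_total,
                abs(pool_total - interception.total_detected() - interception.fp_total),
            )
        except Exception as exc:  # noqa: BLE001 - stratum isolation by design
            logger.error("stratum %s failed: %s", stratum.label, exc)
            bundle.failures[stratum.label] = str(exc)

    bundle.summary = _summarize(bundle)
    _write_bundle(bundle, config)
    return bundle


def _summarize(bundle: RunBundle) -> pd.DataFrame:
    rows = []
    for label, table in sorted(bundle.per_stratum.items()):
        included = table[table["included"]]
        for metric in ("ppv_any", "ppv_first", "ppv_remaining",
                       "tests_per_life_first", "tests_per_life_post"):
            vals = included[metric].dropna()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "stratum": label,
                    "metric": metric,
                    "median": float(vals.median()),
                    "min": float(vals.min()),
                    "argmin": str(vals.idxmin()),
                    "max": float(vals.max()),
                    "argmax": str(vals.idxmax()),
                    "n_csos": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def _write_bundle(bundle: RunBundle, config: RunConfig) -> None:
    out = bundle.out_dir
    long_rows = []
    for label, table in sorted(bundle.per_stratum.items()):
        t = table.reset_index(names="predicted_cso")
        t.insert(0, "stratum", label)
        long_rows.append(t)
        safe = label.replace(" ", "_")
        table.rename_axis("predicted_cso").to_csv(out / f"metrics_{safe}.csv")
    if long_rows:
        pd.concat(long_rows, ignore_index=True).to_csv(out / "metrics_long.csv", index=False)
    for label, table in sorted(bundle.strategy_tables.items()):
        safe = label.replace(" ", "_")
        table.rename_axis("strategy").to_csv(out / f"strategy_{safe}.csv")
    if bundle.summary is not None:
        bundle.summary.to_csv(out / "summary.csv", index=False)

    input_paths = {
        k: getattr(config, k)
        for k in vars(config)
        if k.endswith("_path") and getattr(config, k)
    }
    bundle.manifest = {
        "version": __version__,
        "seed": config.seed,
        "round": config.round,
        "dwell_scenario": config.dwell_scenario,
        "fp_rate": config.fp_rate,
        "alpha": config.alpha,
        "threshold": config.threshold,
        "benchmark": config.benchmark,
        "strata": [s.label for s in config.strata],
        "failures": bundle.failures,
        "inputs": {k: _hash_file(v) for k, v in input_paths.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
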