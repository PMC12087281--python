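"""Synthetic study inputs with known ground truth, and a cohort microsimulator.

Real inputs to the pipeline (registry incidence, test performance, CSO
confusion counts, survival) come from external studies; this module fabricates
a structurally faithful stand-in set with known generating parameters:
incidence spanning three orders of magnitude across classes, stage-increasing
sensitivities, a diagonally dominant confusion matrix with one class never
predicted correctly, one class shedding no detectable signal, sex-restricted
classes, and smoking-sensitive classes.  Realism is structural, not numerical —
no attempt is made to imitate real registry marginals.

The individual-level Monte-Carlo simulator realizes the same natural-history
process person by person with a single phased screen stream (no
independent-capture approximation), serving as the brute-force oracle for the
closed-form pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import ChainMetrics, apply_flags, chain_ppvs, modelable_cso_flags
from .cso import ConfusionCounts, CsoModel, CsoStratifiedPositives, build_cso_model, stratify_positives
from .incidence import (
    INCIDENCE_COLUMNS,
    IncidenceTable,
    SmokingRiskTable,
    StratumSpec,
    stratum_incidence,
)
from .interception import (
    DwellScenario,
    InterceptionResult,
    ScreeningConfig,
    TestPerformance,
    incidence_round_interception,
    shedding_trajectory_weights,
)
from .outcomes import OutcomeMetrics, SurvivalTable, stage_shift_lives_saved, tests_per_life
from .registry import (
    ALL_STAGES,
    NO_CSO,
    SEXES,
    SMOKING_STATUSES,
    STAGES,
    UNSTAGED,
    CancerClassRegistry,
)

# ordered name pool; the first n_csos entries found their own CSO, later ones
# share a founder CSO (cross-talk by construction)
_CLASS_POOL = [
    ("lung", "both"),
    ("breast", "female"),
    ("prostate", "male"),
    ("colorectal", "both"),
    ("thyroid", "both"),     # undetectable class when present
    ("myeloid", "both"),     # zero-diagonal CSO when present
    ("ovary", "female"),
    ("liver", "both"),
    ("pancreas", "both"),
    ("stomach", "both"),
    ("kidney", "both"),
    ("bladder", "both"),
    ("uterus", "female"),
    ("cervix", "female"),
    ("esophagus", "both"),
    ("head_neck", "both"),
    ("melanoma", "both"),
    ("sarcoma", "both"),
    ("lymphoid", "both"),
    ("plasma_cell", "both"),
    ("anus", "both"),
    ("brain", "both"),
    ("neuroendocrine", "both"),
    ("small_cell_lung", "both"),
    ("testis", "male"),
]

DEFAULT_STRATUM = StratumSpec(sex="female", age_lo=65, age_hi=70)

AGE_BANDS = [(lo, lo + 5) for lo in range(40, 85, 5)]

DIFFICULTIES = ("easy", "realistic", "adversarial")


@dataclass
class SyntheticTruth:
    """Complete generating parameter set plus stored ground-truth outputs."""

    registry: CancerClassRegistry
    incidence: IncidenceTable
    smoking: SmokingRiskTable
    perf: TestPerformance
    dwell_scenarios: dict[str, DwellScenario]
    confusion: ConfusionCounts
    survival: SurvivalTable
    cfg: ScreeningConfig
    alpha: float
    sens_counts: dict[tuple[str, str], tuple[int, int]]
    fp_count: int
    tn_count: int
    difficulty: str
    seed: int
    truth_stratum: StratumSpec = DEFAULT_STRATUM
    truth_chain: pd.DataFrame | None = None
    truth_outcomes: pd.DataFrame | None = None

    @property
    def cso_model(self) -> CsoModel:
        return build_cso_model(self.confusion, self.alpha)

    def run_reference_pipeline(
        self, stratum: StratumSpec | None = None
    ) -> tuple[InterceptionResult, CsoStratifiedPositives, ChainMetrics, OutcomeMetrics]:
        """Analytic pipeline on the in-memory truth parameters."""
        stratum = stratum or self.truth_stratum
        rates = stratum_incidence(self.incidence, stratum)
        interception = incidence_round_interception(
            rates, self.perf, self.dwell_scenarios["default"], self.cfg
        )
        strat = stratify_positives(interception, self.cso_model, self.registry)
        metrics = apply_flags(
            chain_ppvs(strat, self.registry),
            modelable_cso_flags(interception, self.confusion, self.survival, self.registry),
        )
        lives = stage_shift_lives_saved(strat, self.survival, self.registry)
        outcomes = tests_per_life(lives, metrics)
        return interception, strat, metrics, outcomes


def _stage_split(rng: np.random.Generator) -> np.ndarray:
    """Stage distribution (I..IV, unstaged) for one class."""
    staged = rng.dirichlet([5, 6, 5, 3])
    unstaged = rng.uniform(0.02, 0.08)
    return np.append(staged * (1 - unstaged), unstaged)


def generate_synthetic_inputs(
    n_classes: int = 8,
    n_csos: int = 6,
    seed: int = 0,
    difficulty: str = "realistic",
    out_dir: str | Path | None = None,
) -> SyntheticTruth:
    """Generate the full input set with known ground truth.

    ``n_classes`` includes the residual "other" class (no expected CSO);
    ``n_csos`` of the remaining classes found their own CSO and later classes
    share a founder's CSO.  ``difficulty``:

    - ``easy``: perfect stage-I sensitivity, identity confusion, no false
      positives — ground-truth PPV-any is 1 wherever defined;
    - ``realistic``: stage-increasing sensitivities averaging near one half,
      ~0.5% false-positive rate, ~89% confusion diagonal;
    - ``adversarial``: non-monotone raw sensitivities, weak diagonal, higher
      false-positive rate, and long dwell times that stress the
      independent-capture approximation.

    When ``out_dir`` is given, every input file is written there through the
    production writers (see :func:`write_inputs`).
    """
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"difficulty must be one of {DIFFICULTIES}")
    if not (n_classes - 1 >= n_csos >= 2):
        raise ValueError("need n_classes - 1 >= n_csos >= 2")
    if n_classes - 1 > len(_CLASS_POOL):
        raise ValueError(f"at most {len(_CLASS_POOL) + 1} classes supported")
    rng = np.random.default_rng(seed)

    mapped = _CLASS_POOL[: n_classes - 1]
    classes = [name for name, _ in mapped] + ["other"]
    founders = [name for name, _ in mapped[:n_csos]]
    cso_map = {name: name for name in founders}
    for i, (name, _) in enumerate(mapped[n_csos:]):
        cso_map[name] = founders[i % n_csos]
    cso_map["other"] = NO_CSO
    sex_restriction = {name: sex for name, sex in mapped if sex != "both"}
    registry = CancerClassRegistry(
        classes=tuple(classes), cso_map=cso_map, sex_restriction=sex_restriction
    )

    undetectable = "thyroid" if "thyroid" in classes else classes[n_classes - 2]
    zero_diag = "myeloid" if "myeloid" in founders else founders[-1]

    # --- incidence: class totals spanning 3 orders of magnitude -------------
    totals = np.sort(10 ** rng.uniform(-0.5, 2.5, size=len(classes)))[::-1]
    rows = []
    for sex in SEXES:
        for age_lo, age_hi in AGE_BANDS:
            age_factor = 1.05 ** (age_lo - 60)  # incidence rises with age
            for cls, total in zip(classes, totals):
                allowed = registry.allowed_for_sex(cls, sex)
                sex_factor = rng.uniform(0.8, 1.2) if allowed else 0.0
                split = _stage_split(rng)
                for stage, frac in zip(ALL_STAGES, split):
                    rows.append(
                        (sex, age_lo, age_hi, "any", cls, stage,
                         total * age_factor * sex_factor * frac)
                    )
    incidence = IncidenceTable(pd.DataFrame(rows, columns=INCIDENCE_COLUMNS), registry)

    # --- smoking relative risks and prevalence weights ----------------------
    rr_rows = []
    for cls in classes:
        if cls in ("lung", "small_cell_lung", "neuroendocrine"):
            rrs = {"never": 1.0, "former": 5.0, "current": 15.0}
        elif cls in ("bladder", "esophagus", "head_neck", "kidney"):
            rrs = {"never": 1.0, "former": 1.5, "current": 2.5}
        else:
            rrs = {"never": 1.0, "former": 1.0, "current": 1.0}
        for status, rr in rrs.items():
            rr_rows.append((cls, status, rr))
    rr = pd.DataFrame(rr_rows, columns=["cancer_class", "smoking", "rr"])
    w_rows = [
        (sex, lo, hi, status, w)
        for sex in SEXES
        for lo, hi in AGE_BANDS
        for status, w in zip(SMOKING_STATUSES, (0.55, 0.30, 0.15))
    ]
    weights = pd.DataFrame(w_rows, columns=["sex", "age_lo", "age_hi", "smoking", "weight"])
    smoking = SmokingRiskTable(rr=rr, weights=weights)

    # --- test performance ---------------------------------------------------
    sens: dict[tuple[str, str], float] = {}
    for cls in classes:
        if cls == undetectable:
            stage_sens = np.zeros(4)
        elif difficulty == "easy":
            stage_sens = np.ones(4)
        else:
            base = rng.uniform(0.1, 0.35)
            stage_sens = np.minimum(0.95, base * np.array([1.0, 2.0, 3.0, 3.6]))
            if difficulty == "adversarial":
                # sampling noise can make raw estimates non-monotone
                stage_sens = np.clip(
                    stage_sens + rng.normal(0, 0.08, size=4), 0.0, 1.0
                )
        for stage, s in zip(STAGES, stage_sens):
            sens[(cls, stage)] = float(s)
    fp_rate = {"easy": 0.0, "realistic": 0.005, "adversarial": 0.01}[difficulty]
    perf = TestPerformance(sens=sens, fp_rate=fp_rate)

    # --- dwell scenarios ----------------------------------------------------
    base_dwell = (4.0, 3.0, 2.0, 1.0) if difficulty == "adversarial" else (2.0, 1.0, 1.0, 0.5)
    default = DwellScenario(
        label="default",
        dwell={(cls, st): d for cls in classes for st, d in zip(STAGES, base_dwell)},
    )
    scenarios = {
        "default": default,
        "fast_aggressive": default.scaled(0.5, label="fast_aggressive"),
    }

    # --- CSO confusion counts, FP predictions, reference prior --------------
    csos = list(registry.csos)
    n_val = {o: int(rng.integers(30, 200)) for o in csos}
    diag = {"easy": 1.0, "realistic": 0.89, "adversarial": 0.6}[difficulty]
    prior_raw = np.array([sum(n_val[o2] for o2 in csos if o2 == o) for o in csos], float)
    prior_raw += 1.0
    prior_freq = pd.Series(prior_raw / prior_raw.sum(), index=csos)
    matrix = pd.DataFrame(0, index=csos, columns=csos, dtype=int)
    for o in csos:
        n = n_val[o]
        if o == zero_diag and difficulty != "easy":
            others = [x for x in csos if x != o]
            p = prior_freq[others].values / prior_freq[others].values.sum()
            counts = rng.multinomial(n, p)
            matrix.loc[o, others] = counts
        elif difficulty == "easy":
            matrix.loc[o, o] = n
        else:
            correct = rng.binomial(n, diag)
            matrix.loc[o, o] = correct
            others = [x for x in csos if x != o]
            p = prior_freq[others].values / prior_freq[others].values.sum()
            matrix.loc[o, others] = rng.multinomial(n - correct, p)
    if difficulty == "easy":
        fp_counts = pd.Series(0, index=csos, dtype=int)
    else:
        fp_counts = pd.Series(
            rng.multinomial(5, prior_freq.values), index=csos, dtype=int
        )
    confusion = ConfusionCounts(matrix=matrix, fp_counts=fp_counts, prior_freq=prior_freq)

    # --- survival -----------------------------------------------------------
    s5_rows = []
    for cls in classes:
        top = rng.uniform(0.75, 0.95)
        bottom = rng.uniform(0.05, 0.30)
        vals = np.sort(rng.uniform(bottom, top, 2))[::-1]
        s5 = [top, vals[0], vals[1], bottom]
        for stage, s in zip(STAGES, s5):
            s5_rows.append((cls, stage, float(s)))
    s5 = pd.DataFrame(s5_rows, columns=["cancer_class", "stage", "s5"]).pivot(
        index="cancer_class", columns="stage", values="s5"
    )[list(STAGES)]
    os_rows = [
        (sex, lo, hi, float(np.clip(0.995 - 0.004 * (lo - 40), 0.5, 1.0)))
        for sex in SEXES
        for lo, hi in AGE_BANDS
    ]
    os5 = pd.DataFrame(os_rows, columns=["sex", "age_lo", "age_hi", "os5"])
    survival = SurvivalTable(s5=s5, os5=os5)

    # --- validation-study evidence counts (for posterior draws) -------------
    sens_counts = {}
    for (cls, stage), s in sens.items():
        total = int(rng.integers(20, 80))
        sens_counts[(cls, stage)] = (int(round(s * total)), total)
    tn_count = 2600
    fp_count = int(round(fp_rate * tn_count / max(1e-12, 1 - fp_rate)))

    truth = SyntheticTruth(
        registry=registry,
        incidence=incidence,
        smoking=smoking,
        perf=perf,
        dwell_scenarios=scenarios,
        confusion=confusion,
        survival=survival,
        cfg=ScreeningConfig(),
        alpha=1.0,
        sens_counts=sens_counts,
        fp_count=fp_count,
        tn_count=tn_count,
        difficulty=difficulty,
        seed=seed,
    )
    _, _, metrics, outcomes = truth.run_reference_pipeline()
    truth.truth_chain = metrics.table
    truth.truth_outcomes = outcomes.table
    if out_dir is not None:
        write_inputs(truth, out_dir)
    return truth


def write_inputs(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write every input file in the formats the production readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["incidence"] = out / "incidence.csv"
    truth.incidence.write(paths["incidence"])

    paths["smoking_rr"] = out / "smoking_rr.csv"
    truth.smoking.rr.to_csv(paths["smoking_rr"], index=False, float_format="%.17g")
    paths["smoking_weights"] = out / "smoking_weights.csv"
    truth.smoking.weights.to_csv(paths["smoking_weights"], index=False, float_format="%.17g")

    paths["performance"] = out / "performance.csv"
    pd.DataFrame(
        [(c, s, v) for (c, s), v in truth.perf.sens.items()],
        columns=["cancer_class", "stage", "sensitivity"],
    ).to_csv(paths["performance"], index=False, float_format="%.17g")

    paths["dwell"] = out / "dwell.csv"
    pd.DataFrame(
        [
            (scn.label, c, s, v)
            for scn in truth.dwell_scenarios.values()
            for (c, s), v in scn.dwell.items()
        ],
        columns=["scenario", "cancer_class", "stage", "dwell_years"],
    ).to_csv(paths["dwell"], index=False, float_format="%.17g")

    paths["confusion"] = out / "confusion.csv"
    conf_long = truth.confusion.matrix.rename_axis(
        index="clinical_cso", columns="predicted_cso"
    ).stack().rename("count").reset_index()
    conf_long.to_csv(paths["confusion"], index=False)

    paths["fp_counts"] = out / "fp_counts.csv"
    truth.confusion.fp_counts.rename("count").rename_axis("predicted_cso").reset_index(
    ).to_csv(paths["fp_counts"], index=False)

    paths["prior"] = out / "prior.csv"
    truth.confusion.prior_freq.rename("freq").rename_axis("predicted_cso").reset_index(
    ).to_csv(paths["prior"], index=False, float_format="%.17g")

    paths["survival"] = out / "survival.csv"
    truth.survival.s5.rename_axis(
        index="cancer_class", columns="stage"
    ).stack().rename("s5").reset_index().to_csv(paths["survival"], index=False, float_format="%.17g")

    paths["os"] = out / "os.csv"
    truth.survival.os5.to_csv(paths["os"], index=False, float_format="%.17g")

    paths["registry"] = out / "registry.csv"
    pd.DataFrame(
        [
            (c, truth.registry.cso_map[c], truth.registry.restriction(c))
            for c in truth.registry.classes
        ],
        columns=["cancer_class", "clinical_cso", "sex_restriction"],
    ).to_csv(paths["registry"], index=False)
    return paths


def load_registry(path: str | Path) -> CancerClassRegistry:
    """Read a ``cancer_class,clinical_cso,sex_restriction`` registry file."""
    df = pd.read_csv(path, float_precision="round_trip")
    return CancerClassRegistry(
        classes=tuple(df["cancer_class"]),
        cso_map=dict(zip(df["cancer_class"], df["clinical_cso"])),
        sex_restriction={
            r.cancer_class: r.sex_restriction
            for r in df.itertuples()
            if r.sex_restriction != "both"
        },
    )


# ---------------------------------------------------------------------------
# Individual-level Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Empirical counterpart of the analytic pipeline outputs.

    Counts are persons, not expectations: ``interception`` holds empirical
    detected / missed cancers, ``tp_by_cso`` the detected cancers by (class,
    predicted CSO), ``fp_by_cso`` the false positives by predicted CSO.
    """

    interception: InterceptionResult
    tp_by_cso: pd.DataFrame
    fp_by_cso: pd.Series
    n_persons: int
    n_cases: int


def simulate_screening_cohort(
    truth: SyntheticTruth,
    n_persons: int,
    seed: int,
    stratum: StratumSpec | None = None,
    dwell_label: str = "default",
) -> SimulatedCohort:
    """Person-by-person realization of one incidence screening round.

    Each person independently develops an incident cancer during the round with
    probability given by the stratum's total incidence; a case gets a class and
    clinical stage from the incidence weights, a shedding-onset stage from the
    trajectory weights, exponential stage sojourns, and a single stream of
    screens at the configured interval with uniform phase.  The first screen
    falling in a detectable stage before clinical diagnosis intercepts the
    cancer at the then-current stage.  No independence approximation is made
    across stages, so discrepancies from the closed-form pipeline isolate that
    approximation (plus Monte-Carlo noise).  Cancer-free and undetected persons
    screen falsely positive with the single FP rate; every positive draws a
    predicted CSO from the smoothed confusion model.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    rng = np.random.default_rng(seed)
    stratum = stratum or truth.truth_stratum
    dwell = truth.dwell_scenarios[dwell_label]
    cfg = truth.cfg
    T = cfg.screen_interval
    model = truth.cso_model
    rates = stratum_incidence(truth.incidence, stratum)

    # joint distribution over (class, clinical stage)
    combos = [
        (cls, stage, rates.loc[cls, stage])
        for cls in rates.index
        for stage in ALL_STAGES
        if rates.loc[cls, stage] > 0
    ]
    rate_total = sum(r for _, _, r in combos)
    p_case = rate_total / 100_000.0 * T
    n_cases = int(rng.binomial(n_persons, p_case))
    weights = np.array([r for _, _, r in combos]) / rate_total
    case_counts = rng.multinomial(n_cases, weights)

    det_rows: list[tuple[str, str, str, float]] = []
    miss_rows: list[tuple[str, str, float]] = []
    tp_cso_rows: list[tuple[str, str, float]] = []

    for (cls, s_clin, _), n_grp in zip(combos, case_counts):
        if n_grp == 0:
            continue
        sens_vec = truth.perf.stage_vector(cls)
        w = shedding_trajectory_weights(sens_vec)
        dw = dwell.stage_vector(cls)
        cso = truth.registry.cso_map[cls]
        p_row = (
            model.p_tp.loc[cso].values
            if cso in model.p_tp.index
            else model.prior.values
        )
        if s_clin == UNSTAGED:
            s_hat_iv = 1.0 - w["never"]
            shedding = rng.random(n_grp) < s_hat_iv
            window = rng.exponential(dw[-1], size=n_grp)
            u = rng.uniform(0, T, size=n_grp)
            detected = shedding & (u < window)
            n_det = int(detected.sum())
            if n_det:
                det_rows.append((cls, UNSTAGED, UNSTAGED, float(n_det)))
                _assign_csos(tp_cso_rows, cls, n_det, p_row, model.labels, rng)
            if n_grp - n_det:
                miss_rows.append((cls, UNSTAGED, float(n_grp - n_det)))
            continue
        s_idx = STAGES.index(s_clin)
        onset_labels = list(STAGES) + ["never"]
        onset_p = np.array([w[o] for o in onset_labels])
        onset_counts = rng.multinomial(n_grp, onset_p)
        n_missed = int(onset_counts[-1])  # never-shedding
        for b_idx in range(len(STAGES)):
            n_onset = int(onset_counts[b_idx])
            if n_onset == 0:
                continue
            if b_idx > s_idx:
                n_missed += n_onset
                continue
            k = s_idx - b_idx + 1  # stages traversed while detectable
            sojourns = rng.exponential(dw[b_idx : s_idx + 1], size=(n_onset, k))
            bounds = np.cumsum(sojourns, axis=1)
            u = rng.uniform(0, T, size=n_onset)
            # stage containing the first screen after shedding onset
            stage_of_u = (u[:, None] >= bounds).sum(axis=1)
            detected_mask = u < bounds[:, -1]
            for j in range(k):
                n_det = int((detected_mask & (stage_of_u == j)).sum())
                if n_det:
                    det_rows.append((cls, STAGES[b_idx + j], s_clin, float(n_det)))
                    _assign_csos(tp_cso_rows, cls, n_det, p_row, model.labels, rng)
            n_missed += int((~detected_mask).sum())
        if n_missed:
            miss_rows.append((cls, s_clin, float(n_missed)))

    detected = (
        pd.DataFrame(
            det_rows,
            columns=["cancer_class", "stage_detected", "stage_clinical", "count"],
        )
        .groupby(["cancer_class", "stage_detected", "stage_clinical"], sort=False)
        .sum()
        .reset_index()
    )
    not_detected = (
        pd.DataFrame(miss_rows, columns=["cancer_class", "stage_clinical", "count"])
        .groupby(["cancer_class", "stage_clinical"], sort=False)
        .sum()
        .reset_index()
    )
    n_detected = int(detected["count"].sum()) if len(detected) else 0
    n_fp = int(rng.binomial(n_persons - n_detected, truth.perf.fp_rate))
    fp_by_cso = pd.Series(
        rng.multinomial(n_fp, model.p_fp.values).astype(float), index=model.labels
    )
    tp_by_cso = (
        pd.DataFrame(tp_cso_rows, columns=["cancer_class", "predicted_cso", "count"])
        .groupby(["cancer_class", "predicted_cso"], sort=False)
        .sum()
        .reset_index()
        if tp_cso_rows
        else pd.DataFrame(columns=["cancer_class", "predicted_cso", "count"])
    )
    interception = InterceptionResult(
        detected=detected,
        not_detected=not_detected,
        fp_total=float(n_fp),
        cohort_size=float(n_persons),
    )
    return SimulatedCohort(
        interception=interception,
        tp_by_cso=tp_by_cso,
        fp_by_cso=fp_by_cso,
        n_persons=n_persons,
        n_cases=n_cases,
    )


def _assign_csos(rows, cls, n, p_row, labels, rng) -> None:
    counts = rng.multinomial(n, p_row)
    for lbl, c in zip(labels, counts):
        if c:
            rows.append((cls, lbl, float(c)))
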