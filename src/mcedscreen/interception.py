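"""Interception model: screen detection and stage shift.

Converts clinical incidence into expected screen-detected ("intercepted")
cancers.  Natural history per cancer: the tumor traverses stages I -> II -> III
-> IV with exponential sojourns (mean dwell time per stage) and is clinically
diagnosed during its clinical stage; it becomes blood-detectable at an onset
stage and stays detectable thereafter ("once shedding, always shedding").
Screens recur at a fixed interval with uniform random phase.  A screen that
falls in a detectable stage at or before the clinical stage intercepts the
cancer at that (possibly earlier) stage.

The closed-form model treats per-stage screen capture as independent across
stages; :mod:`mcedscreen.oracle` provides the exact phase-type computation used
to quantify that approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .registry import STAGES, UNSTAGED

NEVER = "never"  # onset label for cancers that never shed detectable signal

INCIDENCE_ROUND = "incidence"
PREVALENCE_ROUND = "prevalence"


@dataclass(frozen=True)
class TestPerformance:
    """Per-class per-stage detection sensitivity and the single false-positive rate.

    ``sens[(cancer_class, stage)]`` is the fraction of cancers of that class
    shedding detectable signal while in that stage.  ``fp_rate`` is one minus
    specificity, applied once per screened cancer-free person — it does not
    accumulate over signal-origin categories.
    """

    sens: dict[tuple[str, str], float]
    fp_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fp_rate <= 1.0:
            raise ValueError(f"fp_rate must be in [0, 1], got {self.fp_rate}")
        for key, v in self.sens.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"sensitivity out of [0, 1] for {key}: {v}")

    def stage_vector(self, cancer_class: str) -> np.ndarray:
        try:
            return np.array([self.sens[(cancer_class, s)] for s in STAGES])
        except KeyError as e:
            raise ValueError(f"missing sensitivity for class {cancer_class!r}: {e}") from e


@dataclass(frozen=True)
class DwellScenario:
    """Mean sojourn times (years) per class and stage under a named scenario."""

    label: str
    dwell: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for key, v in self.dwell.items():
            if v <= 0:
                raise ValueError(f"dwell time must be positive for {key}: {v}")

    def stage_vector(self, cancer_class: str) -> np.ndarray:
        try:
            return np.array([self.dwell[(cancer_class, s)] for s in STAGES])
        except KeyError as e:
            raise ValueError(f"missing dwell time for class {cancer_class!r}: {e}") from e

    def scaled(self, factor: float, label: str | None = None) -> "DwellScenario":
        return DwellScenario(
            label=label or f"{self.label}*{factor}",
            dwell={k: v * factor for k, v in self.dwell.items()},
        )


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening program parameters: interval (years), cohort size, round type."""

    screen_interval: float = 1.0
    cohort_size: float = 100_000.0
    round: str = INCIDENCE_ROUND

    def __post_init__(self) -> None:
        if self.screen_interval <= 0:
            raise ValueError("screen_interval must be positive")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if self.round not in (INCIDENCE_ROUND, PREVALENCE_ROUND):
            raise ValueError(f"round must be incidence or prevalence, got {self.round!r}")


@dataclass
class InterceptionResult:
    """Expected screen-detected cancers by detected and counterfactual stage.

    ``detected`` columns: cancer_class, stage_detected, stage_clinical, count.
    ``not_detected`` columns: cancer_class, stage_clinical, count (cancers the
    screen misses — interval/usual-care diagnoses, or undetected pool members in
    a prevalence round).  ``fp_total`` is the expected number of false positives
    in the cohort.
    """

    detected: pd.DataFrame
    not_detected: pd.DataFrame
    fp_total: float
    cohort_size: float
    round: str = INCIDENCE_ROUND

    def total_detected(self) -> float:
        return float(self.detected["count"].sum())

    def detected_by_class(self) -> pd.Series:
        return self.detected.groupby("cancer_class", sort=False)["count"].sum()

    def cases_by_class(self) -> pd.Series:
        d = self.detected_by_class()
        m = self.not_detected.groupby("cancer_class", sort=False)["count"].sum()
        return d.add(m, fill_value=0.0)


def stage_capture_prob(d: float, T: float) -> float:
    """Probability that a periodic screen falls inside one exponential stage.

    The stage sojourn is exponential with mean ``d``; screens recur every ``T``
    years with uniform phase, so the wait from stage entry to the next screen is
    U(0, T).  P(screen lands in stage) = E[min(sojourn, T)] / T
    = (d/T) * (1 - exp(-T/d)), capped at 1.
    """
    if d <= 0 or T <= 0:
        raise ValueError(f"dwell and interval must be positive, got d={d}, T={T}")
    return float(min(1.0, (d / T) * (1.0 - np.exp(-T / d))))


def shedding_trajectory_weights(sens: np.ndarray) -> dict[str, float]:
    """Decompose a per-stage sensitivity vector into shedding-onset weights.

    Detectability trajectories are monotone: a cancer starts shedding at some
    onset stage and stays detectable.  The stage-wise detectable fraction is
    therefore non-decreasing; raw sensitivity estimates are projected onto the
    monotone cone by isotonic regression (pool-adjacent-violators), and the
    increments of the monotone envelope are the onset weights:

        weight(onset=j) = s_hat_j - s_hat_{j-1},   weight(never) = 1 - s_hat_IV.
    """
    sens = np.asarray(sens, dtype=float)
    if sens.shape != (len(STAGES),):
        raise ValueError(f"expected {len(STAGES)} stage sensitivities, got {sens.shape}")
    if ((sens < 0) | (sens > 1)).any():
        raise ValueError("sensitivities must be in [0, 1]")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    s_hat = iso.fit_transform(np.arange(len(STAGES)), sens)
    weights: dict[str, float] = {}
    prev = 0.0
    for stage, val in zip(STAGES, s_hat):
        weights[stage] = max(0.0, float(val - prev))
        prev = float(val)
    weights[NEVER] = max(0.0, 1.0 - prev)
    return weights


def monotone_sensitivity(sens: np.ndarray) -> np.ndarray:
    """Isotonic (non-decreasing) envelope of a per-stage sensitivity vector."""
    w = shedding_trajectory_weights(sens)
    return np.cumsum([w[s] for s in STAGES])


def _interception_probs(q: np.ndarray, weights: dict[str, float], s_clin_idx: int
                        ) -> tuple[np.ndarray, float]:
    """P(intercepted at stage j) for j <= s_clin, and P(missed), closed form.

    Independent per-stage capture: a cancer with onset stage b is intercepted at
    the first stage j >= b (j <= clinical stage) whose capture succeeds,
    q_j * prod_{k=b}^{j-1} (1 - q_k).
    """
    p_det = np.zeros(len(STAGES))
    p_miss = weights[NEVER]
    for b_idx in range(len(STAGES)):
        w = weights[STAGES[b_idx]]
        if w == 0.0:
            continue
        if b_idx > s_clin_idx:
            p_miss += w  # sheds only after clinical diagnosis
            continue
        remain = 1.0
        for j in range(b_idx, s_clin_idx + 1):
            p_det[j] += w * remain * q[j]
            remain *= 1.0 - q[j]
        p_miss += w * remain
    return p_det, p_miss


def incidence_round_interception(
    rates: pd.DataFrame,
    perf: TestPerformance,
    dwell: DwellScenario,
    cfg: ScreeningConfig,
) -> InterceptionResult:
    """Expected interceptions in a steady-state (incidence) screening round.

    ``rates`` is the class x stage table from :func:`stratum_incidence`
    (per 100,000 person-years).  One round covers ``screen_interval`` years of
    incidence scaled to ``cohort_size`` persons.  Unstaged incidence is carried
    as detected-at-unstaged (late-stage detectability, no stage shift).
    """
    scale = cfg.cohort_size / 100_000.0 * cfg.screen_interval
    det_rows, miss_rows = [], []
    for cls in rates.index:
        stage_rates = rates.loc[cls]
        if float(stage_rates.sum()) == 0.0:
            continue
        sens = perf.stage_vector(cls)
        dw = dwell.stage_vector(cls)
        weights = shedding_trajectory_weights(sens)
        q = np.array([stage_capture_prob(d, cfg.screen_interval) for d in dw])
        for s_idx, s_clin in enumerate(STAGES):
            cases = float(stage_rates[s_clin]) * scale
            if cases == 0.0:
                continue
            p_det, p_miss = _interception_probs(q, weights, s_idx)
            for j in range(s_idx + 1):
                if p_det[j] > 0:
                    det_rows.append((cls, STAGES[j], s_clin, cases * p_det[j]))
            if p_miss > 0:
                miss_rows.append((cls, s_clin, cases * p_miss))
        # unstaged: detectable with the late-stage shedding fraction, no shift
        cases_u = float(stage_rates[UNSTAGED]) * scale
        if cases_u > 0:
            s_hat_iv = 1.0 - weights[NEVER]
            p_u = s_hat_iv * q[-1]
            if p_u > 0:
                det_rows.append((cls, UNSTAGED, UNSTAGED, cases_u * p_u))
            if p_u < 1:
                miss_rows.append((cls, UNSTAGED, cases_u * (1.0 - p_u)))
    return _assemble(det_rows, miss_rows, perf, cfg, INCIDENCE_ROUND)


def prevalence_round_interception(
    rates: pd.DataFrame,
    perf: TestPerformance,
    dwell: DwellScenario,
    cfg: ScreeningConfig,
) -> InterceptionResult:
    """Expected detections at the first screen of an unscreened population.

    The standing preclinical pool is length-biased: cancers destined for
    clinical diagnosis at stage s_clin spend (on average) the dwell time in each
    stage j <= s_clin before diagnosis, so pool(class, j, s_clin) =
    incidence(class, s_clin) * dwell(j).  Each pool member currently in stage j
    is detected with the monotone detectable fraction s_hat_j; detected stage is
    the current stage, the counterfactual clinical stage is the destined one.
    Conservation here is over the pool: detected + not_detected = pool size.
    """
    scale = cfg.cohort_size / 100_000.0  # pool units: rate (per yr) * dwell (yr)
    det_rows, miss_rows = [], []
    for cls in rates.index:
        stage_rates = rates.loc[cls]
        if float(stage_rates.sum()) == 0.0:
            continue
        s_hat = monotone_sensitivity(perf.stage_vector(cls))
        dw = dwell.stage_vector(cls)
        for s_idx, s_clin in enumerate(STAGES):
            rate = float(stage_rates[s_clin]) * scale
            if rate == 0.0:
                continue
            missed = 0.0
            for j in range(s_idx + 1):
                pool_j = rate * dw[j]
                if pool_j * s_hat[j] > 0:
                    det_rows.append((cls, STAGES[j], s_clin, pool_j * s_hat[j]))
                missed += pool_j * (1.0 - s_hat[j])
            if missed > 0:
                miss_rows.append((cls, s_clin, missed))
        rate_u = float(stage_rates[UNSTAGED]) * scale
        if rate_u > 0:
            pool_u = rate_u * dw[-1]
            if pool_u * s_hat[-1] > 0:
                det_rows.append((cls, UNSTAGED, UNSTAGED, pool_u * s_hat[-1]))
            if pool_u * (1.0 - s_hat[-1]) > 0:
                miss_rows.append((cls, UNSTAGED, pool_u * (1.0 - s_hat[-1])))
    return _assemble(det_rows, miss_rows, perf, cfg, PREVALENCE_ROUND)


def _assemble(det_rows, miss_rows, perf: TestPerformance, cfg: ScreeningConfig,
              round_label: str) -> InterceptionResult:
    detected = pd.DataFrame(
        det_rows, columns=["cancer_class", "stage_detected", "stage_clinical", "count"]
    )
    not_detected = pd.DataFrame(
        miss_rows, columns=["cancer_class", "stage_clinical", "count"]
    )
    total_det = float(detected["count"].sum()) if len(detected) else 0.0
    fp_total = perf.fp_rate * max(0.0, cfg.cohort_size - total_det)
    return InterceptionResult(
        detected=detected,
        not_detected=not_detected,
        fp_total=fp_total,
        cohort_size=cfg.cohort_size,
        round=round_label,
    )


# -- file I/O ---------------------------------------------------------------

def load_performance(path: str | Path, fp_rate: float) -> TestPerformance:
    """Read a ``cancer_class,stage,sensitivity`` file; fp_rate comes from config."""
    df = pd.read_csv(path, float_precision="round_trip")
    sens = {
        (r.cancer_class, r.stage): float(r.sensitivity) for r in df.itertuples()
    }
    return TestPerformance(sens=sens, fp_rate=fp_rate)


def load_dwell(path: str | Path, scenario: str) -> DwellScenario:
    """Read a ``scenario,cancer_class,stage,dwell_years`` file for one scenario."""
    df = pd.read_csv(path, float_precision="round_trip")
    sel = df[df["scenario"] == scenario]
    if len(sel) == 0:
        avail = sorted(set(df["scenario"]))
        raise ValueError(f"dwell scenario {scenario!r} not found; available: {avail}")
    dwell = {(r.cancer_class, r.stage): float(r.dwell_years) for r in sel.itertuples()}
    return DwellScenario(label=scenario, dwell=dwell)
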