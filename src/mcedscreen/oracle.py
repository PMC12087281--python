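"""Exact screen-interception probabilities for a single periodic screen stream.

The closed-form interception model treats per-stage screen capture as
independent events.  For one stream of screens at interval T with uniform
random phase, the exact probabilities are available in closed form through the
phase-type (hypoexponential) distribution of cumulative detectable time:

With onset stage b and clinical stage c, let A_j = sum_{k=b..j} S_k where S_k ~
Exp(mean d_k) are the stage sojourns (S_c is the time from entering the clinical
stage to clinical diagnosis).  The wait from shedding onset to the next screen
is U ~ U(0, T), independent of the sojourns, and the cancer is intercepted at
stage j iff A_{j-1} <= U < A_j.  Hence

    P(intercept at j) = (1/T) * int_0^T [S_{A_j}(u) - S_{A_{j-1}}(u)] du,

with the survival-function integral evaluated exactly as
int_0^T S(u) du = alpha' Q^{-1} (e^{QT} - I) 1 for the bidiagonal sojourn
generator Q.  These routines are the reference against which both the
independent-capture closed form (approximation gap) and the Monte-Carlo cohort
simulator (sampling error) are checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .interception import (
    INCIDENCE_ROUND,
    DwellScenario,
    InterceptionResult,
    ScreeningConfig,
    TestPerformance,
    shedding_trajectory_weights,
)
from .registry import STAGES, UNSTAGED

NEVER = "never"


def _mean_survival_integral(means: np.ndarray, T: float) -> float:
    """(1/T) * int_0^T P(S_1 + ... + S_n > u) du for independent exponentials."""
    n = len(means)
    if n == 0:
        return 0.0
    lam = 1.0 / np.asarray(means, dtype=float)
    Q = np.zeros((n, n))
    for i in range(n):
        Q[i, i] = -lam[i]
        if i + 1 < n:
            Q[i, i + 1] = lam[i]
    alpha = np.zeros(n)
    alpha[0] = 1.0
    ones = np.ones(n)
    integral = alpha @ np.linalg.solve(Q, expm(Q * T) - np.eye(n)) @ ones
    return float(integral / T)


def exact_stage_detection_probs(
    dwell_means: np.ndarray, onset_idx: int, s_clin_idx: int, T: float
) -> tuple[np.ndarray, float]:
    """Exact P(intercept at stage j | onset, clinical stage) and P(miss).

    ``dwell_means`` are per-stage mean sojourns for stages I..IV; the sojourn of
    the clinical stage is the time to clinical diagnosis.  Returns an array over
    stages I..IV (zero outside [onset, clinical]) and the miss probability.
    """
    if not 0 <= onset_idx <= s_clin_idx < len(STAGES):
        raise ValueError("need 0 <= onset <= clinical stage < number of stages")
    if T <= 0:
        raise ValueError("screen interval must be positive")
    p_det = np.zeros(len(STAGES))
    prev = 0.0
    for j in range(onset_idx, s_clin_idx + 1):
        cum = _mean_survival_integral(dwell_means[onset_idx : j + 1], T)
        p_det[j] = max(0.0, cum - prev)
        prev = cum
    return p_det, max(0.0, 1.0 - prev)


def exact_interception_probs(
    q_unused: None,
    weights: dict[str, float],
    dwell_means: np.ndarray,
    s_clin_idx: int,
    T: float,
) -> tuple[np.ndarray, float]:
    """Onset-weight mixture of :func:`exact_stage_detection_probs`."""
    p_det = np.zeros(len(STAGES))
    p_miss = weights.get(NEVER, 0.0)
    for b_idx, stage in enumerate(STAGES):
        w = weights.get(stage, 0.0)
        if w == 0.0:
            continue
        if b_idx > s_clin_idx:
            p_miss += w
            continue
        d, m = exact_stage_detection_probs(dwell_means, b_idx, s_clin_idx, T)
        p_det += w * d
        p_miss += w * m
    return p_det, p_miss


def exact_incidence_round_interception(
    rates: pd.DataFrame,
    perf: TestPerformance,
    dwell: DwellScenario,
    cfg: ScreeningConfig,
) -> InterceptionResult:
    """Exact-counterpart of :func:`incidence_round_interception`.

    Identical in every respect except that interception probabilities come from
    the single-stream phase-type computation instead of the independent-capture
    product form.  The elementwise difference between the two results is the
    documented approximation gap.
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
        for s_idx, s_clin in enumerate(STAGES):
            cases = float(stage_rates[s_clin]) * scale
            if cases == 0.0:
                continue
            p_det, p_miss = exact_interception_probs(None, weights, dw, s_idx,
                                                     cfg.screen_interval)
            for j in range(s_idx + 1):
                if p_det[j] > 0:
                    det_rows.append((cls, STAGES[j], s_clin, cases * p_det[j]))
            if p_miss > 0:
                miss_rows.append((cls, s_clin, cases * p_miss))
        cases_u = float(stage_rates[UNSTAGED]) * scale
        if cases_u > 0:
            s_hat_iv = 1.0 - weights[NEVER]
            # single stage: the independent-capture form is already exact
            p_u = s_hat_iv * _mean_survival_integral(dw[-1:], cfg.screen_interval)
            if p_u > 0:
                det_rows.append((cls, UNSTAGED, UNSTAGED, cases_u * p_u))
            if p_u < 1:
                miss_rows.append((cls, UNSTAGED, cases_u * (1.0 - p_u)))
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
        round=INCIDENCE_ROUND,
    )


def approximation_gap(
    analytic: InterceptionResult, exact: InterceptionResult
) -> pd.DataFrame:
    """Per-class detected-count gap between independent-capture and exact models."""
    a = analytic.detected_by_class().rename("analytic")
    e = exact.detected_by_class().rename("exact")
    out = pd.concat([a, e], axis=1).fillna(0.0)
    out["gap"] = out["analytic"] - out["exact"]
    out["rel_gap"] = out["gap"] / out["exact"].where(out["exact"] > 0)
    return out
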