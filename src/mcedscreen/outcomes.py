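"""Lives saved from stage shift and diagnostic tests needed per life saved.

"Lives saved" is the expected increment in 5-year survivors from detecting a
cancer at an earlier stage: each intercepted cancer contributes
delta = s5(class, detected stage) - s5(class, counterfactual clinical stage),
clamped at zero.  Within each predicted-CSO pool the site-directed step finds
the matched cancers (lives_first) and the subsequent general step finds the
cross-talk cancers (lives_post).  Every individual entering a pool consumes one
directed test; everyone not resolved at step one consumes one general test.

Sensitivity variants: competing risks scale contributions by the age band's
5-year all-cause survival; a shedding-hazard variant replaces the mixture
survival with the ctDNA-detectable subgroup's survival under proportional
hazards on the 5-year scale, holding the observed mixture fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .chain import ChainMetrics
from .cso import CsoStratifiedPositives
from .incidence import StratumSpec
from .interception import TestPerformance, monotone_sensitivity
from .registry import STAGES, UNSTAGED, CancerClassRegistry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalTable:
    """5-year cancer-specific survival by class and stage, plus optional extras.

    ``s5``: DataFrame indexed by cancer class with columns I..IV, values in
    [0, 1].  Survival should be non-increasing in stage; violations are logged
    and tolerated (stage-shift gaps are clamped downstream).  ``os5``: optional
    5-year all-cause survival per (sex, age_lo, age_hi) for competing risks.
    """

    s5: pd.DataFrame
    os5: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.s5[list(STAGES)].values
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("5-year survival must be within [0, 1]")
        diffs = np.diff(vals, axis=1)
        if (diffs > 1e-12).any():
            bad = self.s5.index[(diffs > 1e-12).any(axis=1)].tolist()
            logger.warning("survival increases with stage for classes %s", bad)
        if self.os5 is not None and (
            (self.os5["os5"] < 0).any() or (self.os5["os5"] > 1).any()
        ):
            raise ValueError("all-cause survival must be within [0, 1]")

    def has_stage_resolved(self, cancer_class: str) -> bool:
        return cancer_class in self.s5.index and not self.s5.loc[
            cancer_class, list(STAGES)
        ].isna().any()

    def survival(self, cancer_class: str, stage: str) -> float:
        return float(self.s5.loc[cancer_class, stage])

    def os_factor(self, stratum: StratumSpec) -> float:
        if self.os5 is None:
            raise ValueError("no all-cause survival table loaded")
        sel = self.os5[
            (self.os5["sex"] == stratum.sex)
            & (self.os5["age_lo"] == stratum.age_lo)
            & (self.os5["age_hi"] == stratum.age_hi)
        ]
        if len(sel) == 0:
            raise ValueError(f"no all-cause survival for stratum {stratum.label!r}")
        return float(sel["os5"].iloc[0])


@dataclass
class OutcomeMetrics:
    """Lives saved and tests per life saved, per predicted CSO.

    ``table`` columns: lives_first, lives_post, tests_first, tests_post,
    tests_per_life_first, tests_per_life_post (NaN when the corresponding lives
    are zero — flagged undefined, never infinity), vs_benchmark_first /
    vs_benchmark_post (ratio to the diagnostic-mammography yardstick).
    ``excluded_classes``: classes dropped for missing stage-resolved survival.
    """

    table: pd.DataFrame
    excluded_classes: tuple[str, ...] = ()


def _survival_gap(surv_fn, cls: str, s_det: str, s_clin: str) -> float:
    if s_det == UNSTAGED or s_clin == UNSTAGED:
        return 0.0  # unstaged detections carry no modeled stage shift
    delta = surv_fn(cls, s_det) - surv_fn(cls, s_clin)
    if delta < 0:
        logger.warning(
            "negative survival gap clamped for %s %s->%s (%.4f)", cls, s_clin, s_det, delta
        )
        return 0.0
    return delta


def stage_shift_lives_saved(
    strat: CsoStratifiedPositives,
    surv: SurvivalTable,
    registry: CancerClassRegistry,
    surv_fn=None,
) -> OutcomeMetrics:
    """Expected 5-year-survivor increments per predicted-CSO pool.

    ``lives_first`` sums gaps over matched cancers (clinical CSO = predicted),
    ``lives_post`` over cross-talk cancers found by the later general step.
    ``surv_fn(class, stage)`` overrides the mixture survival lookup (used by the
    shedding-hazard variant).  Classes without stage-resolved survival are
    excluded and reported, never silently zeroed.
    """
    fn = surv_fn or surv.survival
    labels = strat.labels
    lives_first = pd.Series(0.0, index=labels)
    lives_post = pd.Series(0.0, index=labels)
    excluded: set[str] = set()
    for rec in strat.tp.itertuples():
        cls = rec.cancer_class
        if not surv.has_stage_resolved(cls):
            excluded.add(cls)
            continue
        delta = _survival_gap(fn, cls, rec.stage_detected, rec.stage_clinical)
        if delta == 0.0:
            continue
        contribution = rec.count * delta
        if strat.clinical_cso.get(cls) == rec.predicted_cso:
            lives_first[rec.predicted_cso] += contribution
        else:
            lives_post[rec.predicted_cso] += contribution
    table = pd.DataFrame({"lives_first": lives_first, "lives_post": lives_post})
    if excluded:
        logger.warning("classes excluded for missing survival: %s", sorted(excluded))
    return OutcomeMetrics(table=table, excluded_classes=tuple(sorted(excluded)))


def tests_per_life(
    outcomes: OutcomeMetrics,
    chain: ChainMetrics,
    benchmark: float = 240.0,
) -> OutcomeMetrics:
    """Diagnostic tests consumed per expected life saved, per predicted CSO.

    Every individual in a pool takes the site-directed test (tests_first =
    n_pool); the matched true positives resolve there, so tests_post = n_pool -
    n_match.  Ratios are NaN (flagged undefined) where lives are zero.  The
    ``vs_benchmark`` columns divide by the diagnostic-mammography reference of
    240 tests per life saved.
    """
    table = outcomes.table.copy()
    pool = chain.table["n_pool"].reindex(table.index, fill_value=0.0)
    match = chain.table["n_match"].reindex(table.index, fill_value=0.0)
    table["tests_first"] = pool
    table["tests_post"] = pool - match
    with np.errstate(invalid="ignore", divide="ignore"):
        table["tests_per_life_first"] = np.where(
            table["lives_first"] > 0, table["tests_first"] / table["lives_first"], np.nan
        )
        table["tests_per_life_post"] = np.where(
            table["lives_post"] > 0, table["tests_post"] / table["lives_post"], np.nan
        )
    table["vs_benchmark_first"] = table["tests_per_life_first"] / benchmark
    table["vs_benchmark_post"] = table["tests_per_life_post"] / benchmark
    return OutcomeMetrics(table=table, excluded_classes=outcomes.excluded_classes)


def os_adjusted_lives(
    strat: CsoStratifiedPositives,
    surv: SurvivalTable,
    registry: CancerClassRegistry,
    stratum: StratumSpec,
) -> OutcomeMetrics:
    """Competing-risk variant: scale every contribution by the age band's
    5-year all-cause survival.  Always <= the unadjusted lives saved."""
    factor = surv.os_factor(stratum)
    base = stage_shift_lives_saved(strat, surv, registry)
    table = base.table.copy()
    table["lives_first"] *= factor
    table["lives_post"] *= factor
    return OutcomeMetrics(table=table, excluded_classes=base.excluded_classes)


def hr_split_survival(
    s5_mix: float, detectable_fraction: float, h: float
) -> tuple[float, float]:
    """Split mixture 5-year survival into detectable / non-detectable subgroups.

    Proportional hazards on the 5-year survival scale: s_det = s_mix^(h*k),
    s_non = s_mix^k with k > 0 solving

        f * s_mix^(h*k) + (1 - f) * s_mix^k = s_mix,

    so the subgroup mixture reproduces the observed average survival while the
    detectable subgroup carries an h-fold hazard.  h = 1 returns the mixture
    for both subgroups.
    """
    if not 0.0 < detectable_fraction < 1.0:
        raise ValueError("detectable_fraction must lie strictly inside (0, 1)")
    if h < 1.0:
        raise ValueError("hazard ratio h must be >= 1")
    if not 0.0 < s5_mix < 1.0:
        raise ValueError("mixture survival must lie strictly inside (0, 1)")
    if h == 1.0:
        return s5_mix, s5_mix

    f = detectable_fraction

    def g(k: float) -> float:
        return f * s5_mix ** (h * k) + (1.0 - f) * s5_mix**k - s5_mix

    # g(0) = 1 - s > 0 and g -> -s as k -> inf, so a root is bracketed
    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("no root found for hazard-split survival")
    k = brentq(g, 1e-12, hi, xtol=1e-12, rtol=1e-12)
    return float(s5_mix ** (h * k)), float(s5_mix**k)


def hr_adjusted_lives(
    strat: CsoStratifiedPositives,
    surv: SurvivalTable,
    registry: CancerClassRegistry,
    perf: TestPerformance,
    h: float,
) -> OutcomeMetrics:
    """Shedding-hazard variant of lives saved.

    Screen-detected cancers shed ctDNA, so their survival at every stage is the
    detectable subgroup's, obtained from :func:`hr_split_survival` with the
    stage's monotone detectable fraction.  Degenerate fractions (0 or 1) and
    boundary survivals fall back to the mixture value.
    """
    cache: dict[tuple[str, str], float] = {}

    def det_survival(cls: str, stage: str) -> float:
        key = (cls, stage)
        if key not in cache:
            s_mix = surv.survival(cls, stage)
            s_hat = monotone_sensitivity(perf.stage_vector(cls))
            f = float(s_hat[STAGES.index(stage)])
            if not (0.0 < f < 1.0) or not (0.0 < s_mix < 1.0) or h == 1.0:
                cache[key] = s_mix
            else:
                cache[key] = hr_split_survival(s_mix, f, h)[0]
        return cache[key]

    return stage_shift_lives_saved(strat, surv, registry, surv_fn=det_survival)


# -- file I/O ---------------------------------------------------------------

def load_survival(
    s5_path: str | Path, os_path: str | Path | None = None
) -> SurvivalTable:
    """Read ``cancer_class,stage,s5`` (and optional ``sex,age_lo,age_hi,os5``)."""
    df = pd.read_csv(s5_path, float_precision="round_trip")
    s5 = df.pivot(index="cancer_class", columns="stage", values="s5")
    s5 = s5.reindex(columns=list(STAGES))
    os5 = pd.read_csv(os_path, float_precision="round_trip") if os_path is not None else None
    return SurvivalTable(s5=s5, os5=os5)
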