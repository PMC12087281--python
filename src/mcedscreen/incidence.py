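"""Stratified cancer incidence: loading, validation, smoking adjustment.

Incidence is carried as cases per 100,000 person-years by (sex, 5-year age band,
smoking status, cancer class, stage).  Registry-style sources report incidence
without smoking status (``smoking = any``); smoking-specific incidence is derived
from relative risks with a mixture-preserving rescaling, so that the
population-weighted mixture of the smoking-specific rates reconstitutes the
unadjusted rates exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import (
    ALL_STAGES,
    ANY_SMOKING,
    SEXES,
    SMOKING_STATUSES,
    CancerClassRegistry,
)

logger = logging.getLogger(__name__)

INCIDENCE_COLUMNS = [
    "sex",
    "age_lo",
    "age_hi",
    "smoking",
    "cancer_class",
    "stage",
    "rate_per_100k",
]


@dataclass(frozen=True)
class StratumSpec:
    """A (sex, 5-year age band, smoking status) population slice.

    Age bands are closed-open ``[age_lo, age_hi)`` with boundaries on multiples
    of five inside 40-85.
    """

    sex: str
    age_lo: int
    age_hi: int
    smoking: str = ANY_SMOKING

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.smoking not in SMOKING_STATUSES + (ANY_SMOKING,):
            raise ValueError(f"unknown smoking status {self.smoking!r}")
        if self.age_lo % 5 or self.age_hi % 5:
            raise ValueError("age band boundaries must be multiples of 5")
        if not (40 <= self.age_lo < self.age_hi <= 85):
            raise ValueError(
                f"age band must satisfy 40 <= lo < hi <= 85, got [{self.age_lo}, {self.age_hi})"
            )

    @property
    def label(self) -> str:
        # reporting uses the inclusive "lo to hi-1" phrasing
        return f"{self.sex} {self.age_lo}-{self.age_hi - 1} {self.smoking}"


class IncidenceTable:
    """Validated long-format incidence table.

    Wraps a DataFrame with columns ``sex, age_lo, age_hi, smoking, cancer_class,
    stage, rate_per_100k``.  Every (stratum, class) present carries a complete
    stage vector (stages I-IV plus unstaged), rates are nonnegative, and
    sex-restricted classes have zero rates in the excluded sex.
    """

    def __init__(self, df: pd.DataFrame, registry: CancerClassRegistry):
        self.df = df.reset_index(drop=True)
        self.registry = registry
        self._validate()

    def _validate(self) -> None:
        df = self.df
        missing_cols = [c for c in INCIDENCE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"incidence table missing columns: {missing_cols}")
        unknown = sorted(set(df["cancer_class"]) - set(self.registry.classes))
        if unknown:
            raise ValueError(f"unknown cancer class labels: {unknown}")
        bad_stage = sorted(set(df["stage"]) - set(ALL_STAGES))
        if bad_stage:
            raise ValueError(f"unknown stage labels: {bad_stage}")
        if (df["rate_per_100k"] < 0).any():
            rows = df.index[df["rate_per_100k"] < 0].tolist()
            raise ValueError(f"negative rates at rows {rows}")
        # complete stage vectors per (stratum, class)
        counts = df.groupby(
            ["sex", "age_lo", "age_hi", "smoking", "cancer_class"], sort=False
        )["stage"].nunique()
        incomplete = counts[counts != len(ALL_STAGES)]
        if len(incomplete):
            raise ValueError(
                f"incomplete stage vectors for: {incomplete.index.tolist()[:5]}"
            )
        dup = df.duplicated(
            subset=["sex", "age_lo", "age_hi", "smoking", "cancer_class", "stage"]
        )
        if dup.any():
            raise ValueError(f"duplicate records at rows {df.index[dup].tolist()}")
        for sex in SEXES:
            other = "male" if sex == "female" else "female"
            restricted = [
                c for c in self.registry.classes
                if self.registry.restriction(c) == sex
            ]
            viol = df[
                (df["sex"] == other)
                & df["cancer_class"].isin(restricted)
                & (df["rate_per_100k"] > 0)
            ]
            if len(viol):
                raise ValueError(
                    f"nonzero {other} incidence for {sex}-only classes: "
                    f"{sorted(set(viol['cancer_class']))}"
                )

    # -- accessors ---------------------------------------------------------

    def strata(self) -> list[StratumSpec]:
        keys = self.df[["sex", "age_lo", "age_hi", "smoking"]].drop_duplicates()
        return [
            StratumSpec(r.sex, int(r.age_lo), int(r.age_hi), r.smoking)
            for r in keys.itertuples()
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceTable):
            return NotImplemented
        a = self.df.sort_values(INCIDENCE_COLUMNS[:6]).reset_index(drop=True)
        b = other.df.sort_values(INCIDENCE_COLUMNS[:6]).reset_index(drop=True)
        if not a[INCIDENCE_COLUMNS[:6]].equals(b[INCIDENCE_COLUMNS[:6]]):
            return False
        return bool(
            np.allclose(a["rate_per_100k"], b["rate_per_100k"], rtol=1e-12, atol=1e-12)
        )

    def write(self, path: str | Path) -> None:
        self.df[INCIDENCE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class SmokingRiskTable:
    """Relative risks by (class, smoking status) and smoking prevalence weights.

    ``rr`` has columns ``cancer_class, smoking, rr`` (rr > 0); classes absent
    from the table default to RR = 1 (logged).  ``weights`` has columns
    ``sex, age_lo, age_hi, smoking, weight`` and must sum to 1 over smoking
    status within each (sex, age band).
    """

    rr: pd.DataFrame
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.rr["rr"] <= 0).any():
            raise ValueError("relative risks must be strictly positive")
        bad = set(self.rr["smoking"]) - set(SMOKING_STATUSES)
        if bad:
            raise ValueError(f"unknown smoking statuses in RR table: {sorted(bad)}")
        sums = self.weights.groupby(["sex", "age_lo", "age_hi"])["weight"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("smoking weights must sum to 1 within each stratum")
        if (self.weights["weight"] < 0).any():
            raise ValueError("smoking weights must be nonnegative")

    def relative_risk(self, cancer_class: str, smoking: str) -> float:
        sel = self.rr[
            (self.rr["cancer_class"] == cancer_class) & (self.rr["smoking"] == smoking)
        ]
        if len(sel) == 0:
            logger.info("no RR for class %s status %s; defaulting to 1", cancer_class, smoking)
            return 1.0
        return float(sel["rr"].iloc[0])

    def weight(self, sex: str, age_lo: int, age_hi: int, smoking: str) -> float:
        sel = self.weights[
            (self.weights["sex"] == sex)
            & (self.weights["age_lo"] == age_lo)
            & (self.weights["age_hi"] == age_hi)
            & (self.weights["smoking"] == smoking)
        ]
        if len(sel) == 0:
            raise ValueError(f"no smoking weight for {sex} [{age_lo},{age_hi}) {smoking}")
        return float(sel["weight"].iloc[0])


def load_incidence(path: str | Path, registry: CancerClassRegistry) -> IncidenceTable:
    """Read and validate a delimited incidence file.

    Malformed rows are reported with 1-based line numbers (header is line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in INCIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    errors = []
    unknown_mask = ~df["cancer_class"].isin(registry.classes)
    for i in df.index[unknown_mask]:
        errors.append(f"line {i + 2}: unknown cancer class {df.at[i, 'cancer_class']!r}")
    stage_mask = ~df["stage"].isin(ALL_STAGES)
    for i in df.index[stage_mask]:
        errors.append(f"line {i + 2}: unknown stage {df.at[i, 'stage']!r}")
    neg_mask = df["rate_per_100k"] < 0
    for i in df.index[neg_mask]:
        errors.append(f"line {i + 2}: negative rate {df.at[i, 'rate_per_100k']}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return IncidenceTable(df, registry)


def load_smoking_risks(rr_path: str | Path, weights_path: str | Path) -> SmokingRiskTable:
    rr = pd.read_csv(rr_path, float_precision="round_trip")
    weights = pd.read_csv(weights_path, float_precision="round_trip")
    return SmokingRiskTable(rr=rr, weights=weights)


def apply_smoking_adjustment(
    inc: IncidenceTable,
    risks: SmokingRiskTable,
    target_status: str,
) -> IncidenceTable:
    """Derive smoking-status-specific incidence from unstratified rates.

    The unadjusted rate for a class is treated as a prevalence-weighted mixture
    over smoking statuses with known relative risks:

        rate_any = baseline * sum_k w_k * RR_k,

    so ``baseline = rate_any / sum_k w_k RR_k`` and the rate for status ``k`` is
    ``baseline * RR_k``.  This conserves the mixture exactly:
    ``sum_k w_k * adjusted_k = rate_any``.  ``target_status = "any"`` returns the
    input unchanged.
    """
    if target_status == ANY_SMOKING:
        return inc
    if target_status not in SMOKING_STATUSES:
        raise ValueError(f"unknown smoking status {target_status!r}")
    if (inc.df["smoking"] != ANY_SMOKING).any():
        raise ValueError("input incidence must be unstratified by smoking (smoking='any')")

    rows = []
    for (sex, age_lo, age_hi), grp in inc.df.groupby(["sex", "age_lo", "age_hi"], sort=False):
        w = {k: risks.weight(sex, int(age_lo), int(age_hi), k) for k in SMOKING_STATUSES}
        for cls, cgrp in grp.groupby("cancer_class", sort=False):
            rr = {k: risks.relative_risk(cls, k) for k in SMOKING_STATUSES}
            denom = sum(w[k] * rr[k] for k in SMOKING_STATUSES)
            if denom <= 0:
                raise ValueError(
                    f"degenerate smoking mixture for class {cls!r} in "
                    f"{sex} [{age_lo},{age_hi}): sum w*RR = {denom}"
                )
            factor = rr[target_status] / denom
            out = cgrp.copy()
            out["smoking"] = target_status
            out["rate_per_100k"] = cgrp["rate_per_100k"] * factor
            rows.append(out)
    return IncidenceTable(pd.concat(rows, ignore_index=True), inc.registry)


def stratum_incidence(inc: IncidenceTable, stratum: StratumSpec) -> pd.DataFrame:
    """Class x stage rate vector (per 100,000 person-years) for one stratum.

    Returns a DataFrame indexed by cancer class with one column per stage.
    Raises with the list of available strata if the stratum is absent.
    """
    df = inc.df
    sel = df[
        (df["sex"] == stratum.sex)
        & (df["age_lo"] == stratum.age_lo)
        & (df["age_hi"] == stratum.age_hi)
        & (df["smoking"] == stratum.smoking)
    ]
    if len(sel) == 0:
        avail = ", ".join(s.label for s in inc.strata())
        raise ValueError(f"stratum {stratum.label!r} not in table; available: {avail}")
    wide = sel.pivot(index="cancer_class", columns="stage", values="rate_per_100k")
    wide = wide.reindex(index=[c for c in inc.registry.classes if c in wide.index],
                        columns=list(ALL_STAGES))
    if wide.isna().any().any():
        raise ValueError(f"incomplete stage vectors for stratum {stratum.label!r}")
    return wide
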