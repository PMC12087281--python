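"""Diagnostic-chain positive predictive values per predicted CSO.

The diagnostic chain has two step types: a site-directed workup driven by the
predicted CSO (assumed 100% sensitive for the matching cancer class, 0% for all
others) followed, for unresolved individuals, by a general non-site-specific
workup.  For each predicted-CSO pool with A true positives of any class, M true
positives whose clinical CSO matches the prediction, and F false positives:

    PPV_any       = A / (A + F)          entering the chain
    PPV_first     = M / (A + F)          yield of the site-directed step
    PPV_remaining = (A - M) / (A - M + F)  after the matched cancer is ruled out

False positives stay in the pool until the general step rules them out;
cancers are true positives regardless of the predicted CSO they received.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cso import ConfusionCounts, CsoStratifiedPositives
from .interception import InterceptionResult
from .registry import CancerClassRegistry

PPV_COLUMNS = ["ppv_any", "ppv_first", "ppv_remaining"]


@dataclass
class ChainMetrics:
    """Per-predicted-CSO pool sizes, three-tier PPVs and modelability flags.

    ``table`` is indexed by predicted CSO with columns: n_pool, n_any (true
    positives of any class), n_match, fp, ppv_any, ppv_first, ppv_remaining
    (NaN where the pool is empty — undefined, not zero), and boolean flags
    detectable, cso_predictable, survival_available, included.
    """

    table: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)

    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]


def chain_ppvs(strat: CsoStratifiedPositives, registry: CancerClassRegistry) -> ChainMetrics:
    """Three-tier PPVs for every predicted-CSO pool."""
    A = strat.tp_by_cso()
    M = strat.matched_by_cso()
    F = strat.fp.reindex(A.index, fill_value=0.0)
    pool = A + F
    rem = A - M
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv_any = np.where(pool > 0, A / pool, np.nan)
        ppv_first = np.where(pool > 0, M / pool, np.nan)
        rem_pool = rem + F
        ppv_remaining = np.where(rem_pool > 0, rem / rem_pool, np.nan)
    table = pd.DataFrame(
        {
            "n_pool": pool,
            "n_any": A,
            "n_match": M,
            "fp": F,
            "ppv_any": ppv_any,
            "ppv_first": ppv_first,
            "ppv_remaining": ppv_remaining,
        },
        index=A.index,
    )
    table["detectable"] = True
    table["cso_predictable"] = True
    table["survival_available"] = True
    table["included"] = True
    return ChainMetrics(table=table)


def modelable_cso_flags(
    interception: InterceptionResult,
    counts: ConfusionCounts,
    survival=None,
    registry: CancerClassRegistry | None = None,
) -> pd.DataFrame:
    """Modelability flags per CSO, mirroring the exclusions used in reporting.

    detectable: some class with that clinical CSO has nonzero sensitivity
    evidence (it appears among detected cancers).  cso_predictable: the
    confusion row for the CSO has a nonzero diagonal count.  survival_available:
    stage-resolved survival exists for some class mapping to the CSO.
    """
    labels = counts.labels
    flags = pd.DataFrame(
        True, index=labels, columns=["detectable", "cso_predictable", "survival_available"]
    )
    diag = pd.Series(np.diag(counts.matrix.values), index=labels)
    flags["cso_predictable"] = diag > 0
    if registry is not None:
        det_classes = set(interception.detected_by_class().index[
            interception.detected_by_class() > 0
        ])
        for o in labels:
            classes = registry.classes_for_cso(o)
            if classes:
                flags.loc[o, "detectable"] = bool(det_classes & set(classes))
    if survival is not None and registry is not None:
        for o in labels:
            classes = registry.classes_for_cso(o)
            if classes:
                flags.loc[o, "survival_available"] = any(
                    survival.has_stage_resolved(c) for c in classes
                )
    return flags


def apply_flags(metrics: ChainMetrics, flags: pd.DataFrame) -> ChainMetrics:
    """Merge modelability flags into the metric table; included = all flags true."""
    table = metrics.table.copy()
    for col in flags.columns:
        table[col] = flags[col].reindex(table.index, fill_value=True)
    table["included"] = (
        table["detectable"] & table["cso_predictable"] & table["survival_available"]
    )
    return ChainMetrics(table=table)


def summarize_across_csos(
    metrics: ChainMetrics, statistic: str = "ppv_any"
) -> dict[str, object]:
    """Median and labelled range of one PPV tier over included, defined CSOs."""
    if statistic not in metrics.table.columns:
        raise ValueError(f"unknown statistic {statistic!r}")
    vals = metrics.included()[statistic].dropna()
    if len(vals) == 0:
        raise ValueError(f"no included CSOs with defined {statistic}")
    return {
        "statistic": statistic,
        "median": float(vals.median()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "argmin": str(vals.idxmin()),
        "argmax": str(vals.idxmax()),
        "n": int(len(vals)),
    }


def threshold_report(metrics: ChainMetrics, threshold: float = 0.07) -> pd.DataFrame:
    """Inclusive pass/fail of each PPV tier against the workup threshold.

    The default 7% line is the minimal cancer risk conventionally justifying a
    diagnostic workup; comparison is >= (a pool exactly at the line passes).
    Undefined PPVs report as False.
    """
    out = pd.DataFrame(index=metrics.table.index)
    for col in PPV_COLUMNS:
        out[f"{col}_pass"] = metrics.table[col] >= threshold
    return out.fillna(False)
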