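"""Cancer-signal-origin (CSO) assignment for true and false positives.

A validation-study confusion matrix (clinical CSO x predicted CSO counts) is
finite and leaves plausible prediction pairs unobserved.  Observed counts are
therefore augmented with a reference prior — the clinical-CSO frequency among
signal-detected training cases — as pseudo-counts, which keeps every predicted
probability strictly positive.  False positives get the same treatment from the
(sparse) observed FP predictions.  Stratifying all positives by predicted CSO
is then a linear, mass-conserving map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .interception import InterceptionResult
from .registry import NO_CSO, CancerClassRegistry


@dataclass(frozen=True)
class ConfusionCounts:
    """Observed CSO-prediction counts plus the training reference prior.

    ``matrix``: DataFrame, rows = clinical CSO, columns = predicted CSO, integer
    counts from the validation study.  ``fp_counts``: Series over predicted CSO,
    observed predictions among false positives.  ``prior_freq``: Series over
    predicted CSO, clinical-CSO frequencies among signal-detected training
    cases; sums to 1.
    """

    matrix: pd.DataFrame
    fp_counts: pd.Series
    prior_freq: pd.Series

    def __post_init__(self) -> None:
        labels = list(self.matrix.columns)
        if list(self.matrix.index) != labels:
            raise ValueError("confusion matrix must have the same labels on both axes")
        if len(labels) == 0:
            raise ValueError("empty CSO label set")
        if (self.matrix.values < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        if list(self.fp_counts.index) != labels or list(self.prior_freq.index) != labels:
            raise ValueError("fp_counts and prior_freq must share the matrix label set")
        if (self.fp_counts.values < 0).any():
            raise ValueError("FP counts must be nonnegative")
        if (self.prior_freq.values < 0).any() or not np.isclose(
            float(self.prior_freq.sum()), 1.0, atol=1e-9
        ):
            raise ValueError("prior_freq must be a probability vector summing to 1")

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass(frozen=True)
class CsoModel:
    """Smoothed conditional CSO-prediction distributions.

    ``p_tp``: rows = clinical CSO, columns = predicted CSO, each row a strictly
    positive distribution.  ``p_fp``: strictly positive distribution of
    predicted CSO among false positives.  ``alpha``: total pseudo-count weight
    used for the augmentation.  ``prior``: the reference prior itself, kept so
    classes with no confusion row can fall back to it.
    """

    p_tp: pd.DataFrame
    p_fp: pd.Series
    alpha: float
    prior: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.p_tp.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("p_tp rows must sum to 1")
        if not np.isclose(float(self.p_fp.sum()), 1.0, atol=1e-9):
            raise ValueError("p_fp must sum to 1")
        if (self.p_tp.values <= 0).any() or (self.p_fp.values <= 0).any():
            raise ValueError("augmented probabilities must be strictly positive")

    @property
    def labels(self) -> list[str]:
        return list(self.p_tp.columns)


def augment_confusion(counts: ConfusionCounts, alpha: float = 1.0) -> pd.DataFrame:
    """Pseudo-count-smoothed P(predicted CSO | clinical CSO).

    p(o | c) = (n(c, o) + alpha * prior(o)) / (sum_o' n(c, o') + alpha).
    A clinical CSO never observed in validation falls back to the prior row.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if len(counts.labels) == 0:
        raise ValueError("empty CSO label set")
    n = counts.matrix.astype(float)
    prior = counts.prior_freq.astype(float)
    aug = n.add(alpha * prior, axis=1)
    return aug.div(aug.sum(axis=1), axis=0)


def fp_cso_distribution(counts: ConfusionCounts, alpha: float = 1.0) -> pd.Series:
    """Pseudo-count-smoothed P(predicted CSO | false positive).

    p(o) = (fp(o) + alpha * prior(o)) / (sum fp + alpha).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    fp = counts.fp_counts.astype(float)
    aug = fp + alpha * counts.prior_freq.astype(float)
    return aug / aug.sum()


def build_cso_model(counts: ConfusionCounts, alpha: float = 1.0) -> CsoModel:
    return CsoModel(
        p_tp=augment_confusion(counts, alpha),
        p_fp=fp_cso_distribution(counts, alpha),
        alpha=alpha,
        prior=counts.prior_freq.astype(float),
    )


@dataclass
class CsoStratifiedPositives:
    """All expected positives stratified by predicted CSO.

    ``tp``: long DataFrame with columns cancer_class, stage_detected,
    stage_clinical, predicted_cso, count — screen-detected cancers spread over
    predicted CSOs with the stage-shift detail retained.  ``fp``: Series of
    expected false positives per predicted CSO.  ``clinical_cso``: class ->
    clinical CSO row used (registry mapping, with the fallback applied for
    "other"-type classes).
    """

    tp: pd.DataFrame
    fp: pd.Series
    clinical_cso: dict[str, str]

    @property
    def labels(self) -> list[str]:
        return list(self.fp.index)

    def tp_by_cso(self) -> pd.Series:
        s = self.tp.groupby("predicted_cso", sort=False)["count"].sum()
        return s.reindex(self.labels, fill_value=0.0)

    def tp_by_class(self) -> pd.Series:
        return self.tp.groupby("cancer_class", sort=False)["count"].sum()

    def matched_by_cso(self) -> pd.Series:
        """True positives whose clinical CSO equals the predicted CSO."""
        mask = self.tp.apply(
            lambda r: self.clinical_cso.get(r["cancer_class"]) == r["predicted_cso"],
            axis=1,
        )
        if not mask.any():
            return pd.Series(0.0, index=self.labels)
        s = self.tp[mask].groupby("predicted_cso", sort=False)["count"].sum()
        return s.reindex(self.labels, fill_value=0.0)

    def total_positives(self) -> float:
        return float(self.tp["count"].sum() + self.fp.sum())


def stratify_positives(
    interception: InterceptionResult,
    model: CsoModel,
    registry: CancerClassRegistry,
) -> CsoStratifiedPositives:
    """Distribute detected cancers and false positives over predicted CSOs.

    Each detected cancer of class c is spread over predicted CSOs with
    p_tp(. | clinical CSO of c); classes mapping to no CSO ("other") use a
    dedicated confusion row labelled "none"/"other" if present, else the prior
    distribution (realized as the FP row would be: the reference prior itself is
    a valid row because augmentation of an all-zero row returns it).  FPs are
    spread with p_fp; their total is conserved exactly.
    """
    labels = model.labels
    rows = []
    clinical_cso: dict[str, str] = {}
    for rec in interception.detected.itertuples():
        cls = rec.cancer_class
        cso = registry.cso_map.get(cls)
        if cso is None:
            raise ValueError(f"detected class {cls!r} missing from registry")
        if cso in model.p_tp.index:
            row = model.p_tp.loc[cso]
            clinical_cso[cls] = cso
        else:
            fallback = next(
                (lbl for lbl in (NO_CSO, "other") if lbl in model.p_tp.index), None
            )
            if fallback is not None:
                row = model.p_tp.loc[fallback]
                clinical_cso[cls] = fallback
            elif cso == NO_CSO and model.prior is not None:
                row = model.prior
                clinical_cso[cls] = NO_CSO
            else:
                raise ValueError(
                    f"class {cls!r} has clinical CSO {cso!r} with no confusion row "
                    "and no prior fallback"
                )
        for o in labels:
            p = float(row[o])
            if p > 0:
                rows.append(
                    (cls, rec.stage_detected, rec.stage_clinical, o, rec.count * p)
                )
    tp = pd.DataFrame(
        rows,
        columns=["cancer_class", "stage_detected", "stage_clinical", "predicted_cso", "count"],
    )
    fp = interception.fp_total * model.p_fp
    return CsoStratifiedPositives(tp=tp, fp=fp, clinical_cso=clinical_cso)


# -- file I/O ---------------------------------------------------------------

def load_confusion(
    confusion_path: str | Path, fp_path: str | Path, prior_path: str | Path
) -> ConfusionCounts:
    """Read ``clinical_cso,predicted_cso,count`` / ``predicted_cso,count`` /
    ``predicted_cso,freq`` files into :class:`ConfusionCounts`."""
    conf = pd.read_csv(confusion_path, float_precision="round_trip")
    fp = pd.read_csv(fp_path, float_precision="round_trip")
    prior = pd.read_csv(prior_path, float_precision="round_trip")
    labels = list(prior["predicted_cso"])
    matrix = (
        conf.pivot(index="clinical_cso", columns="predicted_cso", values="count")
        .reindex(index=labels, columns=labels)
        .fillna(0.0)
    )
    fp_counts = (
        fp.set_index("predicted_cso")["count"].reindex(labels).fillna(0.0)
    )
    prior_freq = prior.set_index("predicted_cso")["freq"].reindex(labels)
    return ConfusionCounts(matrix=matrix, fp_counts=fp_counts, prior_freq=prior_freq)
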