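"""Posterior uncertainty propagation and dwell-time scenario comparison.

Input parameters are estimated from finite external studies: per-class
per-stage sensitivities from (detected, total) case counts, the false-positive
rate from (FP, cancer-free total) counts, and the CSO confusion rows from
validation counts.  Draws from conjugate posteriors — Beta(count + 1/2) with a
Jeffreys prior for the binomial rates, Dirichlet(counts + alpha * reference
prior) for the CSO rows — are pushed through the full pipeline to produce
interval estimates, and a one-block-at-a-time resampling attributes output
variance to input blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .cso import ConfusionCounts, CsoModel, build_cso_model
from .interception import DwellScenario, TestPerformance

logger = logging.getLogger(__name__)

BLOCKS = ("sensitivity", "fp_rate", "confusion")


@dataclass(frozen=True)
class PosteriorSpec:
    """Evidence counts behind every uncertain input parameter.

    ``sens_counts``: (class, stage) -> (detected, total) cases in the
    validation study.  ``fp_count``/``tn_count``: false positives and true
    negatives among cancer-free participants.  ``confusion``: the observed CSO
    counts (reused for Dirichlet draws).  ``draws``: number of posterior draws.
    """

    sens_counts: dict[tuple[str, str], tuple[int, int]]
    fp_count: int
    tn_count: int
    confusion: ConfusionCounts
    draws: int = 500
    seed: int = 0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        for key, (det, tot) in self.sens_counts.items():
            if det < 0 or tot < det:
                raise ValueError(f"invalid sensitivity counts for {key}: {det}/{tot}")
        if self.fp_count < 0 or self.tn_count < 0:
            raise ValueError("FP / TN counts must be nonnegative")

    def point_estimates(self) -> tuple[TestPerformance, CsoModel]:
        sens = {
            k: (det / tot if tot > 0 else 0.0)
            for k, (det, tot) in self.sens_counts.items()
        }
        denom = self.fp_count + self.tn_count
        fp_rate = self.fp_count / denom if denom > 0 else 0.0
        return (
            TestPerformance(sens=sens, fp_rate=fp_rate),
            build_cso_model(self.confusion, self.alpha),
        )


def posterior_draws(
    spec: PosteriorSpec,
    rng: np.random.Generator | None = None,
    blocks: tuple[str, ...] = BLOCKS,
) -> Iterator[tuple[TestPerformance, CsoModel]]:
    """Stream of (TestPerformance, CsoModel) posterior draws.

    Blocks not listed in ``blocks`` stay at their point estimates, which is how
    the one-at-a-time variance attribution reuses this generator.  With a fixed
    seed the stream is reproducible draw for draw.
    """
    rng = rng or np.random.default_rng(spec.seed)
    perf0, model0 = spec.point_estimates()
    labels = spec.confusion.labels
    prior = spec.confusion.prior_freq.values.astype(float)
    for _ in range(spec.draws):
        if "sensitivity" in blocks:
            sens = {
                k: float(rng.beta(det + 0.5, (tot - det) + 0.5))
                for k, (det, tot) in spec.sens_counts.items()
            }
        else:
            sens = dict(perf0.sens)
        if "fp_rate" in blocks:
            fp_rate = float(rng.beta(spec.fp_count + 0.5, spec.tn_count + 0.5))
        else:
            fp_rate = perf0.fp_rate
        if "confusion" in blocks:
            p_tp = pd.DataFrame(
                [
                    rng.dirichlet(
                        spec.confusion.matrix.loc[c].values.astype(float)
                        + spec.alpha * prior
                    )
                    for c in labels
                ],
                index=labels,
                columns=labels,
            )
            p_fp = pd.Series(
                rng.dirichlet(
                    spec.confusion.fp_counts.values.astype(float) + spec.alpha * prior
                ),
                index=labels,
            )
            model = CsoModel(
                p_tp=p_tp, p_fp=p_fp, alpha=spec.alpha,
                prior=spec.confusion.prior_freq.astype(float),
            )
        else:
            model = model0
        yield TestPerformance(sens=sens, fp_rate=fp_rate), model


@dataclass
class UncertaintySummary:
    """Interval estimates and variance attribution for pipeline outputs.

    ``central``: point-estimate pipeline output (one value per metric).
    ``lo``/``hi``: 2.5% / 97.5% quantiles over the posterior draws.
    ``attribution``: per-metric share of variance by input block, normalized
    over blocks.  ``n_failed``: draws skipped because the pipeline raised.
    """

    central: pd.Series
    lo: pd.Series
    hi: pd.Series
    draws: pd.DataFrame
    attribution: pd.DataFrame
    n_failed: int = 0


def propagate_uncertainty(
    spec: PosteriorSpec,
    pipeline: Callable[[TestPerformance, CsoModel], pd.Series],
    attribution_draws: int | None = None,
) -> UncertaintySummary:
    """Push posterior draws through a pipeline and summarize the outputs.

    ``pipeline`` maps one (performance, CSO model) draw to a flat Series of
    named output metrics.  Variance attribution reruns the stream with a single
    block resampled at a time (others fixed at point estimates); shares are
    each block's output variance normalized over blocks.
    """
    if spec.draws < 2:
        raise ValueError("need at least 2 draws to summarize uncertainty")
    perf0, model0 = spec.point_estimates()
    central = pipeline(perf0, model0)

    def run_stream(blocks: tuple[str, ...], seed_offset: int) -> tuple[pd.DataFrame, int]:
        rng = np.random.default_rng(spec.seed + seed_offset)
        rows, failed = [], 0
        for perf, model in posterior_draws(spec, rng=rng, blocks=blocks):
            try:
                rows.append(pipeline(perf, model))
            except Exception as exc:  # noqa: BLE001 - a bad draw must not kill the run
                failed += 1
                logger.warning("draw skipped: %s", exc)
        return pd.DataFrame(rows), failed

    all_draws, n_failed = run_stream(BLOCKS, 0)
    if len(all_draws) < 2:
        raise RuntimeError("fewer than 2 successful posterior draws")
    lo = all_draws.quantile(0.025)
    hi = all_draws.quantile(0.975)

    n_attr = attribution_draws or spec.draws
    attr_spec = spec if n_attr == spec.draws else PosteriorSpec(
        sens_counts=spec.sens_counts, fp_count=spec.fp_count, tn_count=spec.tn_count,
        confusion=spec.confusion, draws=n_attr, seed=spec.seed, alpha=spec.alpha,
    )
    variances = {}
    for i, block in enumerate(BLOCKS):
        rng = np.random.default_rng(attr_spec.seed + 1000 + i)
        rows = []
        for perf, model in posterior_draws(attr_spec, rng=rng, blocks=(block,)):
            try:
                rows.append(pipeline(perf, model))
            except Exception:  # noqa: BLE001
                continue
        block_df = pd.DataFrame(rows)
        variances[block] = block_df.var() if len(block_df) > 1 else central * 0.0
    attribution = pd.DataFrame(variances)
    total = attribution.sum(axis=1)
    attribution = attribution.div(total.where(total > 0), axis=0)

    return UncertaintySummary(
        central=central, lo=lo, hi=hi, draws=all_draws,
        attribution=attribution, n_failed=n_failed,
    )


def dwell_scenario_compare(
    run_fn: Callable[[DwellScenario], pd.DataFrame],
    scenarios: dict[str, DwellScenario],
    baseline: str,
) -> pd.DataFrame:
    """Per-CSO metric deltas between dwell-time scenarios.

    ``run_fn`` maps a dwell scenario to a per-CSO DataFrame of metrics (e.g.
    ppv_any, lives_first); the returned long table carries each scenario's
    metrics plus their deltas against the baseline scenario.  Shorter dwell
    times leave less time for screens to land, so a uniformly faster scenario
    never increases detections.
    """
    if baseline not in scenarios:
        raise ValueError(f"unknown baseline scenario {baseline!r}")
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    base = run_fn(scenarios[baseline])
    frames = []
    for label, scn in scenarios.items():
        metrics = base if label == baseline else run_fn(scn)
        out = metrics.copy()
        out["scenario"] = label
        for col in metrics.columns:
            out[f"{col}_delta"] = metrics[col] - base[col]
        frames.append(out.reset_index(names="predicted_cso"))
    return pd.concat(frames, ignore_index=True)
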