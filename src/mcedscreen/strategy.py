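"""Workup-strategy comparison: directed-then-general, directed-only, general-only.

Three strategies for resolving the pool of signal-positive individuals:

A. site-directed workup per predicted CSO, then a general workup for everyone
   unresolved (the reference chain);
B. site-directed workup only, then stop — saves the general tests but leaves
   cross-talk cancers undiagnosed and all false positives unresolved;
C. general workup only, ignoring the CSO prediction.

Under the 100%-sensitivity assumption A and C save the same lives; B saves only
the matched (first-step) lives.  The expense break-even ratio r* is the
general:directed cost ratio at which strategies A and C tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import ChainMetrics
from .cso import CsoStratifiedPositives
from .outcomes import OutcomeMetrics

STRATEGIES = ("directed_then_general", "directed_only", "general_only")


@dataclass
class StrategyComparison:
    """Test counts, lives saved and residual risk per workup strategy.

    ``table`` is indexed by strategy with columns directed_tests, general_tests,
    lives_saved, residual_tp (cancers undiagnosed at termination) and
    residual_risk (fraction of the terminal pool with cancer).  ``per_cso``
    gives the directed-only residual risk per predicted CSO (equal to
    PPV-remaining by construction).
    """

    table: pd.DataFrame
    per_cso: pd.DataFrame


def strategy_compare(
    strat: CsoStratifiedPositives,
    chain: ChainMetrics,
    outcomes: OutcomeMetrics,
) -> StrategyComparison:
    """Compare the three workup strategies on one stratified-positives pool."""
    A = float(chain.table["n_any"].sum())
    M = float(chain.table["n_match"].sum())
    F = float(chain.table["fp"].sum())
    pool = float(chain.table["n_pool"].sum())
    lives_first = float(outcomes.table["lives_first"].sum())
    lives_post = float(outcomes.table["lives_post"].sum())
    tests_post = float(chain.table["n_pool"].sum() - chain.table["n_match"].sum())

    cross_talk = A - M
    residual_pool_b = cross_talk + F
    rows = {
        "directed_then_general": {
            "directed_tests": pool,
            "general_tests": tests_post,
            "lives_saved": lives_first + lives_post,
            "residual_tp": 0.0,
            "residual_risk": 0.0,
        },
        "directed_only": {
            "directed_tests": pool,
            "general_tests": 0.0,
            "lives_saved": lives_first,
            "residual_tp": cross_talk,
            "residual_risk": cross_talk / residual_pool_b if residual_pool_b > 0 else np.nan,
        },
        "general_only": {
            "directed_tests": 0.0,
            "general_tests": pool,
            "lives_saved": lives_first + lives_post,
            "residual_tp": 0.0,
            "residual_risk": 0.0,
        },
    }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(STRATEGIES)]
    per_cso = pd.DataFrame(
        {
            "residual_tp": chain.table["n_any"] - chain.table["n_match"],
            "residual_risk": chain.table["ppv_remaining"],
        }
    )
    return StrategyComparison(table=table, per_cso=per_cso)


def expense_breakeven_ratio(comparison: StrategyComparison) -> float:
    """General:directed cost ratio at which directed-then-general ties general-only.

    With directed tests costing 1 and general tests costing r, strategy A costs
    directed_A + r * general_A and strategy C costs r * general_C; the tie is at

        r* = directed_A / (general_C - general_A).

    Returns NaN (flagged undefined) when the general-test counts coincide.
    Scale-invariant in the test counts.
    """
    a = comparison.table.loc["directed_then_general"]
    c = comparison.table.loc["general_only"]
    denom = float(c["general_tests"] - a["general_tests"])
    if denom <= 0:
        return float("nan")
    return float(a["directed_tests"] / denom)
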