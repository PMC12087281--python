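"""Posterior draws, interval propagation, variance attribution, dwell scenarios."""

import numpy as np
import pandas as pd
import pytest

from mcedscreen import (
    PosteriorSpec,
    chain_ppvs,
    dwell_scenario_compare,
    incidence_round_interception,
    posterior_draws,
    propagate_uncertainty,
    stage_shift_lives_saved,
    stratify_positives,
    stratum_incidence,
)


@pytest.fixture(scope="module")
def spec(truth):
    return PosteriorSpec(
        sens_counts=truth.sens_counts,
        fp_count=truth.fp_count,
        tn_count=truth.tn_count,
        confusion=truth.confusion,
        draws=30,
        seed=7,
        alpha=truth.alpha,
    )


@pytest.fixture(scope="module")
def ppv_pipeline(truth):
    """Map one (performance, CSO model) draw to per-CSO PPV-any values."""
    rates = stratum_incidence(truth.incidence, truth.truth_stratum)

    def pipeline(perf, model):
        interception = incidence_round_interception(
            rates, perf, truth.dwell_scenarios["default"], truth.cfg
        )
        strat = stratify_positives(interception, model, truth.registry)
        return chain_ppvs(strat, truth.registry).table["ppv_any"].add_prefix("ppv_any_")

    return pipeline


class TestPosteriorDraws:
    def test_same_seed_reproduces_stream(self, spec):
        a = list(posterior_draws(spec))
        b = list(posterior_draws(spec))
        for (pa, ma), (pb, mb) in zip(a, b):
            assert pa.sens == pb.sens and pa.fp_rate == pb.fp_rate
            assert ma.p_tp.equals(mb.p_tp) and ma.p_fp.equals(mb.p_fp)

    def test_beta_draw_mean_matches_closed_form(self, truth):
        spec = PosteriorSpec(
            sens_counts={("lung", "I"): (30, 60)},
            fp_count=13,
            tn_count=2587,
            confusion=truth.confusion,
            draws=4000,
            seed=3,
        )
        fps = np.array([p.fp_rate for p, _ in posterior_draws(spec, blocks=("fp_rate",))])
        a, b = 13.5, 2587.5
        mean, var = a / (a + b), (a * b) / ((a + b) ** 2 * (a + b + 1))
        assert abs(fps.mean() - mean) < 3 * np.sqrt(var / len(fps))

    def test_large_counts_concentrate_at_point_estimate(self, truth):
        spec = PosteriorSpec(
            sens_counts={("lung", "I"): (300000, 600000)},
            fp_count=truth.fp_count,
            tn_count=truth.tn_count,
            confusion=truth.confusion,
            draws=50,
            seed=3,
        )
        sens = np.array(
            [p.sens[("lung", "I")] for p, _ in posterior_draws(spec, blocks=("sensitivity",))]
        )
        assert np.all(np.abs(sens - 0.5) < 0.005)


class TestPropagation:
    def test_intervals_bracket_central_and_attribution_normalized(self, spec, ppv_pipeline):
        summary = propagate_uncertainty(spec, ppv_pipeline, attribution_draws=15)
        defined = summary.central.dropna().index
        assert (summary.lo[defined] <= summary.hi[defined]).all()
        # draw quantiles should straddle the point estimate for most outputs
        inside = (
            (summary.lo[defined] <= summary.central[defined])
            & (summary.central[defined] <= summary.hi[defined])
        )
        assert inside.mean() > 0.5
        shares = summary.attribution.loc[defined].dropna()
        assert np.allclose(shares.sum(axis=1), 1.0, atol=1e-9)
        assert summary.n_failed == 0

    def test_constant_pipeline_gives_zero_width_intervals(self, spec):
        const = pd.Series({"metric": 0.42})
        summary = propagate_uncertainty(spec, lambda perf, model: const)
        assert summary.lo["metric"] == summary.hi["metric"] == 0.42

    def test_wider_fp_evidence_widens_ppv_spread(self, truth, ppv_pipeline):
        """Same FP-rate point estimate from 100x less evidence: more PPV spread.

        Only the FP-rate block is resampled so the comparison isolates it."""
        def spread(fp, tn):
            spec = PosteriorSpec(
                sens_counts=truth.sens_counts, fp_count=fp, tn_count=tn,
                confusion=truth.confusion, draws=60, seed=5, alpha=truth.alpha,
            )
            rows = [
                ppv_pipeline(perf, model)
                for perf, model in posterior_draws(spec, blocks=("fp_rate",))
            ]
            return pd.DataFrame(rows).std().dropna()

        tight = spread(1300, 258700)
        loose = spread(13, 2587)
        assert (loose > tight).all()

    def test_attribution_shifts_with_evidence(self, truth, ppv_pipeline):
        """Drowning the FP-rate posterior in evidence shrinks its variance share."""
        def shares(fp, tn):
            spec = PosteriorSpec(
                sens_counts=truth.sens_counts, fp_count=fp, tn_count=tn,
                confusion=truth.confusion, draws=25, seed=7, alpha=truth.alpha,
            )
            return propagate_uncertainty(
                spec, ppv_pipeline, attribution_draws=25
            ).attribution.dropna()

        sparse = shares(13, 2587)
        dense = shares(13000, 2587000)
        assert dense["fp_rate"].median() < sparse["fp_rate"].median()


class TestDwellScenarios:
    def run_fn(self, truth):
        rates = stratum_incidence(truth.incidence, truth.truth_stratum)

        def run(dwell):
            interception = incidence_round_interception(
                rates, truth.perf, dwell, truth.cfg
            )
            strat = stratify_positives(interception, truth.cso_model, truth.registry)
            metrics = chain_ppvs(strat, truth.registry)
            lives = stage_shift_lives_saved(strat, truth.survival, truth.registry)
            out = metrics.table[["ppv_any"]].copy()
            out["lives"] = lives.table.sum(axis=1)
            out["detected"] = strat.tp_by_cso()
            return out

        return run

    def test_identical_scenarios_have_zero_deltas(self, truth):
        run = self.run_fn(truth)
        table = dwell_scenario_compare(
            run,
            {"default": truth.dwell_scenarios["default"],
             "copy": truth.dwell_scenarios["default"]},
            baseline="default",
        )
        copy = table[table["scenario"] == "copy"]
        assert np.allclose(copy["ppv_any_delta"].fillna(0.0), 0.0)
        assert np.allclose(copy["lives_delta"], 0.0)

    def test_fast_aggressive_reduces_everything(self, truth):
        run = self.run_fn(truth)
        table = dwell_scenario_compare(
            run, truth.dwell_scenarios, baseline="default"
        )
        fast = table[table["scenario"] == "fast_aggressive"]
        assert (fast["detected_delta"] <= 1e-9).all()
        assert (fast["lives_delta"] <= 1e-9).all()
        assert (fast["ppv_any_delta"].dropna() <= 1e-9).all()

    def test_unbounded_dwell_reaches_sensitivity_ceiling(self, truth):
        """Dwell -> infinity: episode detection approaches the per-stage
        detectable-fraction ceiling (every case with shedding onset at or
        before its clinical stage is caught)."""
        from mcedscreen import monotone_sensitivity

        rates = stratum_incidence(truth.incidence, truth.truth_stratum)
        huge = truth.dwell_scenarios["default"].scaled(1e7, label="huge")
        res = incidence_round_interception(rates, truth.perf, huge, truth.cfg)
        detected = res.detected_by_class()
        for cls in detected.index:
            s_hat = monotone_sensitivity(truth.perf.stage_vector(cls))
            ceiling = 0.0
            for i, stage in enumerate(("I", "II", "III", "IV")):
                ceiling += rates.loc[cls, stage] * s_hat[i]
            ceiling += rates.loc[cls, "unstaged"] * s_hat[3]
            assert detected[cls] <= ceiling + 1e-6
            assert detected[cls] == pytest.approx(ceiling, rel=1e-4)

    def test_unknown_baseline_rejected(self, truth):
        with pytest.raises(ValueError, match="unknown baseline"):
            dwell_scenario_compare(lambda d: None, truth.dwell_scenarios, "warp")
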