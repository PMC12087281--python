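"""Lives saved from stage shift, tests-per-life ratios, OS and HR variants."""

import numpy as np
import pandas as pd
import pytest

from mcedscreen import (
    STAGES,
    ChainMetrics,
    SurvivalTable,
    hr_adjusted_lives,
    hr_split_survival,
    os_adjusted_lives,
    stage_shift_lives_saved,
)
from mcedscreen.registry import CancerClassRegistry

from mcedscreen import tests_per_life as per_life
from conftest import make_positives

REG = CancerClassRegistry(classes=("ca",), cso_map={"ca": "x"})


def survival_table(rows, os5=None):
    s5 = pd.DataFrame(rows, columns=["cancer_class"] + list(STAGES)).set_index(
        "cancer_class"
    )
    return SurvivalTable(s5=s5, os5=os5)


class TestLivesSaved:
    def test_ten_cancers_shifted_four_to_one(self):
        """10 cancers IV -> I with s5 0.9 vs 0.2, matched prediction: 7 lives."""
        strat = make_positives(
            [("ca", "I", "IV", "x", 10.0)], {"x": 0.0}, ["x"], {"ca": "x"}
        )
        surv = survival_table([("ca", 0.9, 0.7, 0.5, 0.2)])
        out = stage_shift_lives_saved(strat, surv, REG)
        assert out.table.loc["x", "lives_first"] == pytest.approx(7.0)
        assert out.table.loc["x", "lives_post"] == 0.0

    def test_stage_flat_survival_saves_nothing(self):
        strat = make_positives(
            [("ca", "I", "IV", "x", 10.0)], {"x": 0.0}, ["x"], {"ca": "x"}
        )
        surv = survival_table([("ca", 0.5, 0.5, 0.5, 0.5)])
        assert stage_shift_lives_saved(strat, surv, REG).table.values.sum() == 0.0

    def test_no_stage_shift_saves_nothing(self):
        strat = make_positives(
            [("ca", "III", "III", "x", 10.0)], {"x": 0.0}, ["x"], {"ca": "x"}
        )
        surv = survival_table([("ca", 0.9, 0.7, 0.5, 0.2)])
        assert stage_shift_lives_saved(strat, surv, REG).table.values.sum() == 0.0

    def test_cross_talk_goes_to_post_step(self):
        reg = CancerClassRegistry(classes=("ca", "cb"), cso_map={"ca": "x", "cb": "y"})
        strat = make_positives(
            [("cb", "I", "IV", "x", 5.0)], {"x": 0.0, "y": 0.0}, ["x", "y"],
            {"ca": "x", "cb": "y"},
        )
        surv = survival_table([("ca", 0.9, 0.7, 0.5, 0.2), ("cb", 0.8, 0.6, 0.4, 0.3)])
        out = stage_shift_lives_saved(strat, surv, reg)
        assert out.table.loc["x", "lives_post"] == pytest.approx(2.5)
        assert out.table.loc["x", "lives_first"] == 0.0

    def test_missing_survival_excludes_class_with_flag(self):
        reg = CancerClassRegistry(classes=("ca", "cb"), cso_map={"ca": "x", "cb": "y"})
        strat = make_positives(
            [("ca", "I", "IV", "x", 10.0), ("cb", "I", "IV", "y", 10.0)],
            {"x": 0.0, "y": 0.0},
            ["x", "y"],
            {"ca": "x", "cb": "y"},
        )
        surv = survival_table([("ca", 0.9, 0.7, 0.5, 0.2)])
        out = stage_shift_lives_saved(strat, surv, reg)
        assert out.excluded_classes == ("cb",)
        assert out.table.loc["y", "lives_first"] == 0.0


class TestTestsPerLife:
    @staticmethod
    def chain_for(pool, match, labels=("x",)):
        table = pd.DataFrame({"n_pool": pool, "n_match": match}, index=list(labels))
        table["included"] = True
        return ChainMetrics(table=table)

    def test_division_and_benchmark(self):
        """30-person pool, 2 lives: 15 tests per life, far under 240."""
        out = stage_shift_lives_saved(
            make_positives([("ca", "I", "IV", "x", 10.0)], {"x": 0.0}, ["x"], {"ca": "x"}),
            survival_table([("ca", 0.9, 0.8, 0.75, 0.7)]),
            REG,
        )
        metrics = per_life(out, self.chain_for([30.0], [10.0]))
        assert metrics.table.loc["x", "tests_per_life_first"] == pytest.approx(15.0)
        assert metrics.table.loc["x", "vs_benchmark_first"] == pytest.approx(15 / 240)

    def test_all_lives_saved_gives_unit_ratio(self):
        out = stage_shift_lives_saved(
            make_positives([("ca", "I", "IV", "x", 10.0)], {"x": 0.0}, ["x"], {"ca": "x"}),
            survival_table([("ca", 1.0, 0.5, 0.5, 0.0)]),
            REG,
        )
        metrics = per_life(out, self.chain_for([10.0], [10.0]))
        assert metrics.table.loc["x", "tests_per_life_first"] == pytest.approx(1.0)

    def test_zero_lives_is_flagged_undefined(self):
        out = stage_shift_lives_saved(
            make_positives([("ca", "III", "III", "x", 10.0)], {"x": 5.0}, ["x"], {"ca": "x"}),
            survival_table([("ca", 0.9, 0.7, 0.5, 0.2)]),
            REG,
        )
        metrics = per_life(out, self.chain_for([15.0], [10.0]))
        val = metrics.table.loc["x", "tests_per_life_first"]
        assert np.isnan(val) and not np.isinf(val)

    def test_halving_survival_gap_doubles_ratio(self):
        strat = make_positives(
            [("ca", "I", "IV", "x", 10.0)], {"x": 0.0}, ["x"], {"ca": "x"}
        )
        chain = self.chain_for([10.0], [10.0])
        wide = per_life(
            stage_shift_lives_saved(strat, survival_table([("ca", 0.9, 0.7, 0.5, 0.1)]), REG),
            chain,
        ).table.loc["x", "tests_per_life_first"]
        narrow = per_life(
            stage_shift_lives_saved(strat, survival_table([("ca", 0.5, 0.4, 0.3, 0.1)]), REG),
            chain,
        ).table.loc["x", "tests_per_life_first"]
        assert narrow == pytest.approx(2 * wide, rel=1e-12)


class TestOsAdjustment:
    def test_unit_os_is_identity_and_fraction_scales(self, truth, stratified):
        base = stage_shift_lives_saved(stratified, truth.survival, truth.registry)
        os_one = truth.survival.os5.copy()
        os_one["os5"] = 1.0
        surv_one = SurvivalTable(s5=truth.survival.s5, os5=os_one)
        adj = os_adjusted_lives(stratified, surv_one, truth.registry, truth.truth_stratum)
        assert np.allclose(adj.table.values, base.table.values)

        os_08 = truth.survival.os5.copy()
        os_08["os5"] = 0.8
        surv_08 = SurvivalTable(s5=truth.survival.s5, os5=os_08)
        adj = os_adjusted_lives(stratified, surv_08, truth.registry, truth.truth_stratum)
        assert np.allclose(adj.table.values, 0.8 * base.table.values)

    def test_mixed_age_contributions_sum(self, truth):
        """Stratum-by-stratum OS weighting matches the hand-weighted sum."""
        from mcedscreen import StratumSpec, incidence_round_interception, stratify_positives, stratum_incidence

        total, hand = 0.0, 0.0
        for age_lo in (55, 65, 75):
            stratum = StratumSpec("female", age_lo, age_lo + 5)
            rates = stratum_incidence(truth.incidence, stratum)
            strat = stratify_positives(
                incidence_round_interception(
                    rates, truth.perf, truth.dwell_scenarios["default"], truth.cfg
                ),
                truth.cso_model,
                truth.registry,
            )
            adj = os_adjusted_lives(strat, truth.survival, truth.registry, stratum)
            base = stage_shift_lives_saved(strat, truth.survival, truth.registry)
            total += adj.table.values.sum()
            hand += truth.survival.os_factor(stratum) * base.table.values.sum()
        assert total == pytest.approx(hand, rel=1e-12)

    def test_missing_os_rejected(self, truth, stratified):
        surv = SurvivalTable(s5=truth.survival.s5, os5=None)
        with pytest.raises(ValueError):
            os_adjusted_lives(stratified, surv, truth.registry, truth.truth_stratum)


class TestHazardSplit:
    def test_unit_hazard_returns_mixture(self):
        assert hr_split_survival(0.6, 0.5, 1.0) == (0.6, 0.6)

    def test_mixture_constraint_holds(self):
        for s, f, h in [(0.6, 0.5, 2.0), (0.9, 0.2, 1.5), (0.1, 0.8, 3.0)]:
            s_det, s_non = hr_split_survival(s, f, h)
            assert f * s_det + (1 - f) * s_non == pytest.approx(s, abs=1e-10)
            assert s_det < s < s_non  # shedders fare worse, non-shedders better

    def test_matches_independent_secant_solver(self):
        """Bisection-style brentq result against a hand-rolled secant iteration."""
        s, f, h = 0.6, 0.5, 2.0

        def g(k):
            return f * s ** (h * k) + (1 - f) * s**k - s

        k0, k1 = 0.1, 1.0
        for _ in range(80):
            g0, g1 = g(k0), g(k1)
            if g1 == g0 or abs(g1) < 1e-15:
                break
            k0, k1 = k1, k1 - g1 * (k1 - k0) / (g1 - g0)
        s_det, s_non = hr_split_survival(s, f, h)
        assert s_det == pytest.approx(s ** (h * k1), abs=1e-8)
        assert s_non == pytest.approx(s**k1, abs=1e-8)

    def test_detectable_fraction_near_one_recovers_mixture(self):
        s_det, _ = hr_split_survival(0.6, 0.999, 2.0)
        assert s_det == pytest.approx(0.6, abs=5e-3)

    @pytest.mark.parametrize("bad", [dict(s5_mix=0.6, detectable_fraction=0.0, h=2),
                                     dict(s5_mix=1.0, detectable_fraction=0.5, h=2),
                                     dict(s5_mix=0.6, detectable_fraction=0.5, h=0.5)])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            hr_split_survival(**bad)

    def test_hr_variant_changes_lives_not_ppv(self, truth, stratified, reference_run):
        """Shedding-hazard variant alters lives saved; PPVs are untouched by
        construction (survival enters only the outcome layer)."""
        base = stage_shift_lives_saved(stratified, truth.survival, truth.registry)
        hr = hr_adjusted_lives(stratified, truth.survival, truth.registry, truth.perf, h=2.0)
        assert not np.allclose(hr.table.values, base.table.values)
        unit = hr_adjusted_lives(stratified, truth.survival, truth.registry, truth.perf, h=1.0)
        assert np.allclose(unit.table.values, base.table.values)
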