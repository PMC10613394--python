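import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caries_cea import (
    InterventionSpec,
    ModelConfig,
    StateOccupancy,
    discount_factor,
    dmft_increment,
    run_arm,
    sugar_dmft_reduction,
    transition_step,
)
from caries_cea.schedules import AgeRow

from conftest import make_flat_schedule
from oracle import oracle_totals


class TestDiscountFactor:
    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0, 0.05) == 1.0

    @given(t=st.integers(0, 50))
    def test_zero_rate_identity(self, t):
        assert discount_factor(t, 0.0) == 1.0

    def test_closed_form(self):
        assert discount_factor(1, 0.05) == pytest.approx(1 / 1.05)
        assert discount_factor(3, 0.05) == pytest.approx(1.05**-3)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)


class TestSugarReduction:
    def test_null_policy(self):
        assert sugar_dmft_reduction(0.0, ModelConfig()) == 0.0

    def test_published_slope_times_30g(self):
        # 0.0128 DMFT per g/day x 30 g/day
        assert sugar_dmft_reduction(30.0, ModelConfig()) == pytest.approx(0.384)

    @given(x=st.floats(0, 1e3, allow_nan=False))
    def test_linearity(self, x):
        cfg = ModelConfig()
        assert sugar_dmft_reduction(2 * x, cfg) == pytest.approx(
            2 * sugar_dmft_reduction(x, cfg)
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sugar_dmft_reduction(-1.0, ModelConfig())


ROW = AgeRow(age=5, prob_caries=0.2, prob_exit=0.0, baseline_dmft=1.0)


class TestTransitionStep:
    def test_hand_worked_single_step(self):
        """Spreadsheet-style arithmetic: state (100, 50, 10, 0), onset 0.2,
        no exits, untreated 0.7, recurrence 0.188:
        entrants 20, caries->treated 15, treated->caries 1.88."""
        cfg = ModelConfig()
        state = StateOccupancy(100.0, 50.0, 10.0, 0.0)
        out = transition_step(state, ROW, 0.0, cfg)
        assert out.no_caries == pytest.approx(80.0)
        assert out.caries == pytest.approx(56.88)
        assert out.treated == pytest.approx(23.12)
        assert out.exited == 0.0

    def test_full_protection_only_leaks_to_exit(self):
        cfg = ModelConfig()
        row = dataclasses.replace(ROW, prob_exit=0.1)
        state = StateOccupancy(100.0)
        out = transition_step(state, row, 1.0, cfg)
        assert out.no_caries == pytest.approx(90.0)
        assert out.caries == 0.0
        assert out.treated == 0.0
        assert out.exited == pytest.approx(10.0)

    def test_exit_probability_one_flushes_cohort(self):
        cfg = ModelConfig()
        row = dataclasses.replace(ROW, prob_exit=1.0)
        state = StateOccupancy(60.0, 30.0, 10.0, 0.0)
        out = transition_step(state, row, 0.0, cfg)
        assert out.living == pytest.approx(0.0)
        assert out.exited == pytest.approx(100.0)

    @given(
        nc=st.floats(0, 1e4), c=st.floats(0, 1e4), tr=st.floats(0, 1e4),
        p=st.floats(0, 1), q=st.floats(0, 1), e=st.floats(0, 1),
        exit_first=st.booleans(),
    )
    def test_conservation_and_nonnegativity(self, nc, c, tr, p, q, e, exit_first):
        cfg = ModelConfig(exit_first=exit_first)
        row = AgeRow(age=5, prob_caries=p, prob_exit=q, baseline_dmft=1.0)
        state = StateOccupancy(nc, c, tr, 0.0)
        out = transition_step(state, row, e, cfg)
        assert out.total == pytest.approx(state.total, rel=1e-12, abs=1e-12)
        for s in ("no_caries", "caries", "treated", "exited"):
            assert getattr(out, s) >= -1e-12


class TestDmftIncrement:
    def test_full_protection_zero_increment(self):
        cfg = ModelConfig()
        assert dmft_increment(StateOccupancy(100.0), ROW, 1.0, 0, cfg) == 0.0

    def test_stationarity_without_growth(self):
        cfg = ModelConfig(dmft_growth=0.0)
        state = StateOccupancy(100.0, 5.0, 1.0, 0.0)
        a = dmft_increment(state, ROW, 0.2, 0, cfg)
        b = dmft_increment(state, ROW, 0.2, 5, cfg)
        assert a == b

    def test_published_annual_growth_ratio(self):
        """Secular DMFT growth of 0.59%/year between consecutive cycles."""
        cfg = ModelConfig()
        state = StateOccupancy(100.0, 5.0, 1.0, 0.0)
        r0 = dmft_increment(state, ROW, 0.0, 0, cfg)
        r1 = dmft_increment(state, ROW, 0.0, 1, cfg)
        assert r1 / r0 == pytest.approx(1.0059)

    @given(e=st.floats(0, 1))
    def test_linear_in_one_minus_effect(self, e):
        cfg = ModelConfig()
        state = StateOccupancy(100.0)
        base = dmft_increment(state, ROW, 0.0, 0, cfg)
        assert dmft_increment(state, ROW, e, 0, cfg) == pytest.approx(
            base * (1 - e)
        )


class TestRunArm:
    def test_do_nothing_is_the_zero_reference(self, config, flat_schedule):
        trace, res = run_arm(None, flat_schedule, config)
        assert res.total_cost == 0.0
        assert res.dmft_averted == 0.0
        assert res.average_lifetime_cost == 0.0
        assert trace.total_dmft > 0  # caries still accrues

    def test_two_cycle_hand_ledger(self, mini_config):
        """Cohort 10, p_caries 0.2, p_exit 0.1, dmft 1, growth 0, cost 100,
        5% discount, no screening; totals worked by hand:
        cycle 0: living 9, cost 900, entrants 1.8;
        cycle 1: living 8.1, cost 771.4286, entrants 1.296 (x1/1.05)."""
        cfg = dataclasses.replace(mini_config, dmft_growth=0.0)
        sched = make_flat_schedule(2, 0.2, 0.1, dmft=1.0)
        spec = InterventionSpec(
            name="x", annual_cost_mean=100.0, effect_mean=0.0, effect_sd=1.0,
            requires_screening=False,
        ).resolve_sd()
        trace, _ = run_arm(spec, sched, cfg)
        assert trace.total_cost == pytest.approx(900.0 + 771.428571428, rel=1e-9)
        assert trace.total_dmft == pytest.approx(1.8 + 1.296 / 1.05, rel=1e-9)

    def test_zero_cost_zero_effect_matches_do_nothing_plus_screening(
        self, config, flat_schedule
    ):
        from caries_cea.engine import screening_outlay

        neutral = InterventionSpec(
            name="neutral", annual_cost_mean=0.0, effect_mean=0.0, effect_sd=1.0,
            requires_screening=True,
        ).resolve_sd()
        trace, res = run_arm(neutral, flat_schedule, config)
        base, _ = run_arm(None, flat_schedule, config)
        assert res.dmft_averted == pytest.approx(0.0, abs=1e-9)
        assert trace.total_dmft == pytest.approx(base.total_dmft, rel=1e-12)
        assert res.total_cost == pytest.approx(
            screening_outlay(flat_schedule, config, discounted=True), rel=1e-12
        )

    def test_average_lifetime_cost_identity(self, config, specs, flat_schedule):
        for spec in specs:
            _, res = run_arm(spec, flat_schedule, config)
            assert res.average_lifetime_cost * config.cohort_size == pytest.approx(
                res.total_cost, rel=1e-12
            )

    def test_discounting_never_increases_cost(self, config, specs, flat_schedule):
        undiscounted = dataclasses.replace(config, discount_rate=0.0)
        for spec in specs:
            trace, _ = run_arm(spec, flat_schedule, config)
            trace0, _ = run_arm(spec, flat_schedule, undiscounted)
            assert trace.total_cost <= trace0.total_cost + 1e-9
            # at rate 0 discounted and undiscounted ledgers coincide
            assert trace0.total_cost == pytest.approx(
                trace0.total_cost_undiscounted, rel=1e-12
            )

    def test_closed_form_cost_with_zero_exits(self, config):
        """With no exits and constant per-learner cost c, total cost is
        N * c * sum_t (1+r)^-t."""
        sched = make_flat_schedule(10, 0.2, 0.0)
        spec = InterventionSpec(
            name="c", annual_cost_mean=100.0, effect_mean=10.0, effect_sd=1.0,
            requires_screening=False,
        ).resolve_sd()
        trace, _ = run_arm(spec, sched, config)
        annuity = sum(1.05**-t for t in range(10))
        assert trace.total_cost == pytest.approx(
            config.cohort_size * 100.0 * annuity, rel=1e-12
        )

    @given(
        e1=st.floats(0, 1), e2=st.floats(0, 1),
        c1=st.floats(0, 500), c2=st.floats(0, 500),
    )
    def test_monotone_in_effect_and_cost(self, config, flat_schedule, e1, e2, c1, c2):
        spec = InterventionSpec(
            name="m", annual_cost_mean=1.0, effect_mean=50.0, effect_sd=1.0,
            requires_screening=False,
        ).resolve_sd()
        lo_e, hi_e = sorted((e1, e2))
        _, res_lo = run_arm(spec, flat_schedule, config, effect_override=lo_e)
        _, res_hi = run_arm(spec, flat_schedule, config, effect_override=hi_e)
        assert res_hi.dmft_averted >= res_lo.dmft_averted - 1e-9

        lo_c, hi_c = sorted((c1, c2))
        _, r_lo = run_arm(spec, flat_schedule, config, cost_override=lo_c)
        _, r_hi = run_arm(spec, flat_schedule, config, cost_override=hi_c)
        assert r_hi.total_cost >= r_lo.total_cost - 1e-9

    def test_mismatched_schedule_length_rejected(self, config):
        sched = make_flat_schedule(3, 0.2, 0.0)
        with pytest.raises(ValueError, match="schedule length"):
            run_arm(None, sched, config)

    def test_accrual_mechanism_averted_is_effect_times_baseline(self, flat_schedule):
        cfg = ModelConfig(effect_mechanism="accrual")
        spec = InterventionSpec(
            name="a", annual_cost_mean=1.0, effect_mean=72.0, effect_sd=1.0,
            requires_screening=False,
        ).resolve_sd()
        base, _ = run_arm(None, flat_schedule, cfg)
        _, res = run_arm(spec, flat_schedule, cfg)
        assert res.dmft_averted == pytest.approx(0.72 * base.total_dmft, rel=1e-12)

    def test_sugar_offset_mechanism(self, config, specs, flat_schedule):
        """The sugar arm subtracts slope x grams x living learners per
        cycle (discounted), never averting more than baseline accrual."""
        sugar = next(s for s in specs if s.is_sugar_policy)
        base, _ = run_arm(None, flat_schedule, config)
        trace, res = run_arm(sugar, flat_schedule, config, baseline=base)
        assert 0 < res.dmft_averted <= base.total_dmft + 1e-9
        # per-cycle increments are floored at zero
        assert all(x >= 0.0 for x in trace.cycle_dmft)


class TestOracleEquivalence:
    """Engine totals match an independent matrix-propagation oracle."""

    @given(
        cohort=st.integers(1, 10),
        n_cycles=st.integers(1, 3),
        p=st.floats(0, 1), q=st.floats(0, 0.9), e=st.floats(0, 1),
        cost=st.floats(0, 1000), rate=st.floats(0, 0.2),
        exit_first=st.booleans(),
    )
    def test_totals_match(self, cohort, n_cycles, p, q, e, cost, rate, exit_first):
        cfg = ModelConfig(
            cohort_size=cohort, start_age=5, exit_age=5 + n_cycles,
            discount_rate=rate, exit_first=exit_first,
        )
        sched = make_flat_schedule(n_cycles, p, q, dmft=1.7)
        spec = InterventionSpec(
            name="o", annual_cost_mean=cost, effect_mean=0.0, effect_sd=1.0,
            requires_screening=False,
        ).resolve_sd()
        trace, _ = run_arm(spec, sched, cfg, effect_override=e)
        exp_cost, exp_dmft = oracle_totals(
            cohort, [(p, q, 1.7)] * n_cycles, e, cost, rate,
            cfg.prob_untreated, cfg.prob_recurrence, cfg.dmft_growth,
            exit_first=exit_first,
        )
        assert trace.total_cost == pytest.approx(exp_cost, rel=1e-9, abs=1e-9)
        assert trace.total_dmft == pytest.approx(exp_dmft, rel=1e-9, abs=1e-9)
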