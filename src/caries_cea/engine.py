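"""Four-state Markov cohort engine for the caries model.

A closed cohort of learners starts caries-free at age 5 and is advanced
through annual cycles until age 15 across four mutually exclusive states:

    no_caries -> caries -> treated -> (caries again, via recurrence)
                                  \\
    every living state ------------> exited   (absorbing)

Cohort arithmetic is fractional (expected-value cohort model). Per cycle,
living learners accrue the arm's per-learner programme cost (plus the
screening cost for arms that bundle screening); new caries cases accrue
the age-specific baseline mean DMFT, inflated by the secular DMFT growth
rate. Costs and DMFT increments are discounted at the annual rate with
cycle 0 undiscounted; there is no half-cycle correction.

The effectiveness of an intervention is applied, per
``ModelConfig.effect_mechanism``, either as a proportional reduction of
the caries-onset flow (``"flow"``, the default: protected learners stay
at risk in later cycles, so cumulative DMFT averted compensates below
``effect x baseline``) or as a direct scaling of DMFT accrual with
unchanged state dynamics (``"accrual"``: DMFT averted is then exactly
``effect x do-nothing DMFT``, the structure the published averted counts
follow). The sugar-reduction policy instead subtracts an absolute DMFT
offset (slope x grams/day reduced) per living learner per year; its
mechanism is selected through ``ModelConfig.sugar_mechanism``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .config import InterventionSpec, ModelConfig
from .errors import CariesCEAError
from .schedules import AgeSchedule

STATES = ("no_caries", "caries", "treated", "exited")

#: relative tolerance for the cohort-conservation internal check
_CONSERVATION_RTOL = 1e-9


def discount_factor(cycle_index: int, rate: float) -> float:
    """``1/(1+rate)**cycle_index``; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be >= 0, got {cycle_index}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return 1.0 / (1.0 + rate) ** cycle_index


def sugar_dmft_reduction(reduction_g_per_day: float, config: ModelConfig) -> float:
    """Annual per-learner DMFT averted by an added-sugar cut.

    Linear dose-response: each g/day of added sugar contributes
    ``config.sugar_slope`` DMFT per year.
    """
    if reduction_g_per_day < 0:
        raise ValueError(
            f"sugar reduction must be >= 0 g/day, got {reduction_g_per_day}"
        )
    return config.sugar_slope * reduction_g_per_day


@dataclass
class StateOccupancy:
    """Fractional learner counts in the four model states."""

    no_caries: float
    caries: float = 0.0
    treated: float = 0.0
    exited: float = 0.0

    @property
    def living(self) -> float:
        return self.no_caries + self.caries + self.treated

    @property
    def total(self) -> float:
        return self.living + self.exited

    def check(self, cohort_size: float) -> None:
        vals = (self.no_caries, self.caries, self.treated, self.exited)
        if any(x < -_CONSERVATION_RTOL * cohort_size for x in vals):
            raise CariesCEAError(f"negative occupancy: {vals}")
        if abs(self.total - cohort_size) > _CONSERVATION_RTOL * cohort_size:
            raise CariesCEAError(
                f"cohort not conserved: {self.total} != {cohort_size}"
            )


def _apply_exit(state: StateOccupancy, prob_exit: float) -> StateOccupancy:
    keep = 1.0 - prob_exit
    leavers = state.living * prob_exit
    return StateOccupancy(
        no_caries=state.no_caries * keep,
        caries=state.caries * keep,
        treated=state.treated * keep,
        exited=state.exited + leavers,
    )


def _apply_morbidity(
    state: StateOccupancy, prob_caries: float, effect: float, config: ModelConfig
) -> StateOccupancy:
    entrants = state.no_caries * prob_caries * (1.0 - effect)
    caries_to_treated = state.caries * (1.0 - config.prob_untreated)
    treated_to_caries = state.treated * config.prob_recurrence
    return StateOccupancy(
        no_caries=state.no_caries - entrants,
        caries=state.caries - caries_to_treated + entrants + treated_to_caries,
        treated=state.treated - treated_to_caries + caries_to_treated,
        exited=state.exited,
    )


def transition_step(
    state: StateOccupancy,
    age_params,
    effect: float,
    config: ModelConfig,
) -> StateOccupancy:
    """One annual cycle of state flows.

    ``age_params`` is a single age-schedule row with ``prob_caries`` and
    ``prob_exit`` attributes. Exit is applied to every living state before
    (default) or after morbidity flows, per ``config.exit_first``; the
    exited state is absorbing. Conservation is checked exactly.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError(f"effect must be in [0, 1], got {effect}")
    cohort = state.total
    if config.exit_first:
        out = _apply_morbidity(
            _apply_exit(state, age_params.prob_exit),
            age_params.prob_caries, effect, config,
        )
    else:
        out = _apply_exit(
            _apply_morbidity(state, age_params.prob_caries, effect, config),
            age_params.prob_exit,
        )
    out.check(cohort)
    return out


def dmft_increment(
    state: StateOccupancy,
    age_params,
    effect: float,
    cycle_index: int,
    config: ModelConfig,
) -> float:
    """Undiscounted DMFT accrued by new caries cases this cycle.

    Entrants (the no_caries -> caries flow, net of same-cycle exits when
    exit is applied first) each accrue the age's baseline mean DMFT,
    inflated by the annual secular growth ``(1+dmft_growth)**cycle_index``.
    Recurrent caries does not re-accrue DMFT: the index counts lifetime
    decayed/missing/filled teeth, and recurrence affects already-counted
    teeth.
    """
    nc = state.no_caries * (1.0 - age_params.prob_exit) if config.exit_first \
        else state.no_caries
    entrants = nc * age_params.prob_caries * (1.0 - effect)
    return (
        entrants
        * age_params.baseline_dmft
        * (1.0 + config.dmft_growth) ** cycle_index
    )


@dataclass
class CohortTrace:
    """Per-cycle record of one arm's run."""

    name: str
    states: list  # StateOccupancy after each cycle (index 0 = after cycle 0)
    cycle_costs: list  # discounted ZAR
    cycle_costs_undiscounted: list
    cycle_dmft: list  # discounted DMFT increments
    cycle_dmft_undiscounted: list

    @property
    def total_cost(self) -> float:
        return sum(self.cycle_costs)

    @property
    def total_cost_undiscounted(self) -> float:
        return sum(self.cycle_costs_undiscounted)

    @property
    def total_dmft(self) -> float:
        return sum(self.cycle_dmft)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export (one row per cycle and state)."""
        rows = []
        for t, (occ, cost, dmft) in enumerate(
            zip(self.states, self.cycle_costs, self.cycle_dmft)
        ):
            for s in STATES:
                rows.append(
                    {
                        "arm": self.name,
                        "cycle": t,
                        "state": s,
                        "occupancy": getattr(occ, s),
                        "discounted_cost": cost,
                        "discounted_dmft": dmft,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ArmResult:
    """Discounted totals for one arm, referenced to do-nothing."""

    name: str
    total_cost: float
    dmft_averted: float
    average_lifetime_cost: float


DO_NOTHING = "do_nothing"


def run_arm(
    spec: Optional[InterventionSpec],
    schedule: AgeSchedule,
    config: ModelConfig,
    effect_override: Optional[float] = None,
    cost_override: Optional[float] = None,
    baseline: Optional[CohortTrace] = None,
) -> tuple[CohortTrace, ArmResult]:
    """Run one arm over the full horizon.

    ``spec=None`` runs the do-nothing comparator (zero cost, zero effect,
    no screening). ``effect_override`` (a proportion in [0, 1]) and
    ``cost_override`` (ZAR per learner per year) replace the spec's means;
    the PSA uses them to propagate sampled parameters. ``baseline`` is a
    previously computed do-nothing trace on the same schedule; if omitted
    it is recomputed internally.
    """
    if len(schedule) != config.n_cycles:
        raise ValueError(
            f"schedule length {len(schedule)} != n_cycles {config.n_cycles}"
        )

    if spec is None:
        name = DO_NOTHING
        annual_cost = 0.0
        effect = 0.0
        sugar_offset = 0.0
    else:
        name = spec.name
        annual_cost = (
            cost_override if cost_override is not None else spec.annual_cost_mean
        )
        if annual_cost < 0:
            raise ValueError(f"negative annual cost for arm {name}")
        if spec.requires_screening:
            annual_cost += config.screening_cost
        if spec.is_sugar_policy and effect_override is None \
                and config.sugar_mechanism == "offset":
            # linear dose-response mechanism: absolute DMFT offset per
            # living learner, no reduction of the onset flow
            effect = 0.0
            sugar_offset = sugar_dmft_reduction(config.sugar_reduction, config)
        else:
            effect = (
                effect_override
                if effect_override is not None
                else spec.effect_mean / 100.0
            )
            sugar_offset = 0.0
        if not 0.0 <= effect <= 1.0:
            raise ValueError(f"effect for arm {name} must be in [0, 1], got {effect}")

    # under accrual scaling the state dynamics are those of do-nothing;
    # effectiveness only multiplies the DMFT increments
    flow_effect = effect if config.effect_mechanism == "flow" else 0.0

    state = StateOccupancy(no_caries=float(config.cohort_size))
    states, costs, costs_u, dmfts, dmfts_u = [], [], [], [], []
    for t, row in enumerate(schedule.rows()):
        df = discount_factor(t, config.discount_rate)
        inc = dmft_increment(state, row, flow_effect, t, config)
        if config.effect_mechanism == "accrual":
            inc *= 1.0 - effect
        new_state = transition_step(state, row, flow_effect, config)
        # living learners present during the cycle (post-exit convention
        # when exit is applied first) carry programme + screening cost
        living = new_state.living if config.exit_first else state.living
        cost = annual_cost * living
        if sugar_offset:
            # offset cannot avert more DMFT than would have accrued
            inc = max(0.0, inc - sugar_offset * living)
        states.append(new_state)
        costs.append(cost * df)
        costs_u.append(cost)
        dmfts.append(inc * df)
        dmfts_u.append(inc)
        state = new_state

    trace = CohortTrace(name, states, costs, costs_u, dmfts, dmfts_u)

    if spec is None:
        averted = 0.0
    else:
        if baseline is None:
            baseline, _ = run_arm(None, schedule, config)
        averted = baseline.total_dmft - trace.total_dmft
    result = ArmResult(
        name=name,
        total_cost=trace.total_cost,
        dmft_averted=averted,
        average_lifetime_cost=trace.total_cost / config.cohort_size,
    )
    return trace, result


def run_all_arms(
    specs, schedule: AgeSchedule, config: ModelConfig
) -> tuple[dict[str, CohortTrace], list[ArmResult]]:
    """Do-nothing plus every configured arm on one schedule."""
    base_trace, base_result = run_arm(None, schedule, config)
    traces = {DO_NOTHING: base_trace}
    results = [base_result]
    for spec in specs:
        trace, res = run_arm(spec, schedule, config, baseline=base_trace)
        traces[spec.name] = trace
        results.append(res)
    return traces, results


def screening_outlay(
    schedule: AgeSchedule, config: ModelConfig, discounted: bool = False
) -> float:
    """Total 10-year screening expenditure for the cohort.

    The living count depends only on the exit schedule, so this is the
    calibration observable for the exit probabilities. Undiscounted by
    default (the published 10-year screening figure exceeds the
    discounted ceiling, so it can only be an undiscounted outlay).
    """
    total = 0.0
    living = float(config.cohort_size)
    for t, row in enumerate(schedule.rows()):
        living *= 1.0 - row.prob_exit
        df = discount_factor(t, config.discount_rate) if discounted else 1.0
        total += living * config.screening_cost * df
    return total
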