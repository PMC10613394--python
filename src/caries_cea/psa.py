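"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: each arm's annual
per-learner cost is drawn from a gamma distribution and its effectiveness
from a beta distribution, both moment-matched to the published mean/SD
(costs can never go negative under a gamma; effectiveness draws lie in
[0, 1] by construction and are never clipped). Each draw is pushed
through the Markov engine via the override mechanism; the age schedules
and structural probabilities stay fixed. The default is 1000 iterations.

Outputs: per-iteration (cost, DMFT averted) samples for the
cost-effectiveness plane, cost-effectiveness acceptability curves (the
probability that an arm has the highest net monetary benefit among all
mutually exclusive options, do-nothing included), and a ranked summary
table of sample means/SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cea
from .config import InterventionSpec, ModelConfig
from .engine import DO_NOTHING, ArmResult, run_arm
from .errors import SamplingError
from .schedules import AgeSchedule

#: default willingness-to-pay grid: ZAR0 to ZAR40,000 in steps of 500,
#: covering both discussion points (ZAR500 and the ZAR38,500 threshold)
DEFAULT_WTP_GRID = np.arange(0.0, 40_000.0 + 1, 500.0)


def gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale) for a cost parameter."""
    if mean <= 0 or sd <= 0:
        raise SamplingError(
            f"gamma requires mean > 0 and sd > 0, got mean={mean}, sd={sd}"
        )
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def beta_params(mean_pct: float, sd_pct: float) -> tuple[float, float]:
    """Moment-matched beta (alpha, beta) for an effectiveness parameter.

    Inputs are on the percent scale as published; they are converted to
    proportions before matching. An SD at or above the binomial-style
    bound sqrt(m(1-m)) is infeasible for a beta and raises (no silent
    clipping), naming the feasible bound.
    """
    m = mean_pct / 100.0
    s = sd_pct / 100.0
    if not 0.0 < m < 1.0:
        raise SamplingError(
            f"beta requires mean strictly inside (0, 100)%, got {mean_pct}%"
        )
    bound = np.sqrt(m * (1.0 - m))
    if s <= 0 or s >= bound:
        raise SamplingError(
            f"beta SD {sd_pct}% infeasible for mean {mean_pct}%: "
            f"must be in (0, {100 * bound:.4f}%)"
        )
    nu = m * (1.0 - m) / s**2 - 1.0
    return m * nu, (1.0 - m) * nu


@dataclass
class PSASamples:
    """Rectangular Monte Carlo samples: one row per iteration, per arm."""

    arms: list  # arm names, do-nothing excluded
    costs: np.ndarray  # (n_iterations, n_arms) discounted total cost
    dmft_averted: np.ndarray  # (n_iterations, n_arms)
    n_iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (iteration, arm, cost, dmft_averted)."""
        n, k = self.costs.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), k),
                "arm": np.tile(self.arms, n),
                "total_cost": self.costs.ravel(),
                "dmft_averted": self.dmft_averted.ravel(),
            }
        )


def run_psa(
    config: ModelConfig,
    specs: list[InterventionSpec],
    schedule: AgeSchedule,
    n_iterations: int = 1000,
    seed: int = 0,
) -> PSASamples:
    """Monte Carlo propagation of cost/effectiveness uncertainty.

    One random stream (seeded numpy Generator), arm-major draw order:
    for each arm, first its ``n_iterations`` cost draws, then its
    effectiveness draws. Identical seeds therefore give bit-identical
    samples. The sugar arm's sampled effectiveness is applied through the
    flow-reduction mechanism like any other arm.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    rng = np.random.default_rng(seed)

    draws = {}
    for spec in specs:
        try:
            shape, scale = gamma_params(spec.annual_cost_mean, spec.annual_cost_sd)
        except SamplingError as exc:
            raise SamplingError(f"arm {spec.name!r}, cost: {exc}") from exc
        try:
            alpha, beta = beta_params(spec.effect_mean, spec.effect_sd)
        except SamplingError as exc:
            raise SamplingError(f"arm {spec.name!r}, effectiveness: {exc}") from exc
        cost_draws = rng.gamma(shape, scale, n_iterations)
        effect_draws = rng.beta(alpha, beta, n_iterations)
        draws[spec.name] = (cost_draws, effect_draws)

    baseline, _ = run_arm(None, schedule, config)
    costs = np.empty((n_iterations, len(specs)))
    averted = np.empty((n_iterations, len(specs)))
    for j, spec in enumerate(specs):
        cost_draws, effect_draws = draws[spec.name]
        for i in range(n_iterations):
            _, res = run_arm(
                spec,
                schedule,
                config,
                effect_override=float(effect_draws[i]),
                cost_override=float(cost_draws[i]),
                baseline=baseline,
            )
            costs[i, j] = res.total_cost
            averted[i, j] = res.dmft_averted

    return PSASamples(
        arms=[s.name for s in specs],
        costs=costs,
        dmft_averted=averted,
        n_iterations=n_iterations,
        seed=seed,
    )


@dataclass
class CEACCurve:
    """Acceptability curves over a WTP grid (arms sum to 1 everywhere)."""

    wtp_grid: np.ndarray
    probabilities: pd.DataFrame  # one column per arm incl. do-nothing

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "wtp", self.wtp_grid)
        return out


def ceac(
    samples: PSASamples,
    wtp_grid=None,
    pairwise: bool = False,
) -> CEACCurve:
    """Cost-effectiveness acceptability curves.

    Default convention: at each threshold an arm's probability is the
    fraction of iterations in which it attains the strictly highest NMB
    among all mutually exclusive options including do-nothing (NMB 0);
    exact ties share the count equally, so the curves sum to 1 across
    arms at every threshold. ``pairwise=True`` instead reports, per arm,
    the fraction of iterations with NMB > 0 versus do-nothing alone
    (curves then need not sum to 1).
    """
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if samples.n_iterations == 0:
        raise ValueError("samples are empty")

    names = list(samples.arms) + [DO_NOTHING]
    n = samples.n_iterations
    probs = np.zeros((wtp_grid.size, len(names)))
    for gi, wtp in enumerate(wtp_grid):
        nmb = wtp * samples.dmft_averted - samples.costs
        nmb = np.hstack([nmb, np.zeros((n, 1))])  # do-nothing: NMB 0
        if pairwise:
            probs[gi] = (nmb > 0).mean(axis=0)
            probs[gi, -1] = 1.0  # do-nothing vs itself: reference
        else:
            best = nmb.max(axis=1, keepdims=True)
            winners = nmb == best
            probs[gi] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(
        wtp_grid=wtp_grid,
        probabilities=pd.DataFrame(probs, columns=names),
    )


def summarize_psa(samples: PSASamples, wtp: float, cohort_size: float) -> pd.DataFrame:
    """Ranked summary of the Monte Carlo samples.

    Per arm: mean/SD of cost and DMFT averted, mean average lifetime
    cost, the vs-do-nothing and ranked ICERs of the sample means, and the
    mean NMB (equal to WTP x mean effect - mean cost by linearity).
    Sample SDs use ddof=1.
    """
    mean_results = [ArmResult(DO_NOTHING, 0.0, 0.0, 0.0)]
    sds = {DO_NOTHING: (0.0, 0.0)}
    for j, name in enumerate(samples.arms):
        c = samples.costs[:, j]
        e = samples.dmft_averted[:, j]
        mean_results.append(
            ArmResult(
                name=name,
                total_cost=float(c.mean()),
                dmft_averted=float(e.mean()),
                average_lifetime_cost=float(c.mean()) / cohort_size,
            )
        )
        ddof = 1 if len(c) > 1 else 0
        sds[name] = (float(c.std(ddof=ddof)), float(e.std(ddof=ddof)))

    table = cea.cea_table(mean_results, wtp=wtp).table
    table["sd_cost"] = [sds[n][0] for n in table["name"]]
    table["sd_dmft"] = [sds[n][1] for n in table["name"]]
    return table.drop(columns=["dominated", "extended_dominated"])
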