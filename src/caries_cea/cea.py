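"""Deterministic cost-effectiveness statistics.

Given per-arm discounted totals (cost, DMFT averted) this module computes

* pairwise ICERs versus the do-nothing comparator,
* ranked incremental ICERs: arms sorted ascending by effectiveness, each
  compared with the previous arm in the ordering (negative ICERs are
  reported as such — the source tables keep all arms rather than pruning
  to the efficiency frontier; a frontier mode additionally flags strict
  and extended dominance),
* net monetary benefit, NMB = WTP x effect - cost.

Full precision is retained internally; ``round_icer`` provides the two
display conventions used by the published tables (2 decimals below 10
for the vs-do-nothing column, nearest integer for the ranked column).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .engine import DO_NOTHING, ArmResult
from .errors import UndefinedICERError


def icer(cost_a: float, effect_a: float, cost_b: float, effect_b: float) -> float:
    """Incremental cost-effectiveness ratio of a versus b.

    Sign is preserved (a negative ICER means the more effective option is
    also cheaper, or vice versa). Equal effectiveness raises
    :class:`UndefinedICERError` carrying the cost difference.
    """
    d_effect = effect_a - effect_b
    if d_effect == 0.0:
        raise UndefinedICERError(cost_a - cost_b)
    return (cost_a - cost_b) / d_effect


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * effect - cost


def round_icer(value: float, style: str = "vs_donothing") -> float:
    """Display rounding for ICER columns.

    ``vs_donothing``: 2 decimals when |value| < 10, else nearest integer.
    ``ranked``: nearest integer always.
    """
    if style == "vs_donothing" and abs(value) < 10:
        return round(value, 2)
    if style in ("vs_donothing", "ranked"):
        return float(round(value))
    raise ValueError(f"unknown rounding style {style!r}")


def rank_by_effectiveness(results: Iterable[ArmResult]) -> list[ArmResult]:
    """Ascending by DMFT averted; ties broken by lower cost first."""
    return sorted(results, key=lambda r: (r.dmft_averted, r.total_cost))


def _strictly_dominated(rows: Sequence[ArmResult]) -> list[bool]:
    flags = []
    for r in rows:
        flags.append(
            any(
                (o.total_cost <= r.total_cost and o.dmft_averted > r.dmft_averted)
                or (o.total_cost < r.total_cost and o.dmft_averted >= r.dmft_averted)
                for o in rows
            )
        )
    return flags


def _extended_dominated(rows: Sequence[ArmResult], strict: Sequence[bool]) -> list[bool]:
    """Arms above the convex frontier: iteratively drop any arm whose
    incremental ICER along the effectiveness ordering exceeds the next
    arm's, until the ICER sequence is non-decreasing."""
    alive = [i for i, s in enumerate(strict) if not s]
    changed = True
    while changed and len(alive) > 2:
        changed = False
        for k in range(1, len(alive) - 1):
            prev_i, i, next_i = alive[k - 1], alive[k], alive[k + 1]
            try:
                icer_in = icer(
                    rows[i].total_cost, rows[i].dmft_averted,
                    rows[prev_i].total_cost, rows[prev_i].dmft_averted,
                )
                icer_out = icer(
                    rows[next_i].total_cost, rows[next_i].dmft_averted,
                    rows[prev_i].total_cost, rows[prev_i].dmft_averted,
                )
            except UndefinedICERError:
                continue
            if icer_in > icer_out:
                alive.pop(k)
                changed = True
                break
    on_frontier = set(alive)
    return [
        (i not in on_frontier) and not strict[i] for i in range(len(rows))
    ]


@dataclass
class CEAResult:
    """Ranked deterministic results table."""

    table: pd.DataFrame
    wtp: float

    def to_csv(self, path, display: bool = False):
        frame = self.display_table() if display else self.table
        frame.to_csv(path, index=False)

    def display_table(self) -> pd.DataFrame:
        """Rounded variant matching the published tables' formatting."""
        out = self.table.copy()
        out["icer_vs_donothing"] = [
            "Ref" if math.isnan(x) else round_icer(x, "vs_donothing")
            for x in out["icer_vs_donothing"]
        ]
        out["ranked_icer"] = [
            "Ref" if math.isnan(x) else round_icer(x, "ranked")
            for x in out["ranked_icer"]
        ]
        out["nmb"] = out["nmb"].round().astype("int64")
        out["total_cost"] = out["total_cost"].round().astype("int64")
        out["dmft_averted"] = out["dmft_averted"].round().astype("int64")
        out["average_lifetime_cost"] = (
            out["average_lifetime_cost"].round().astype("int64")
        )
        return out


def cea_table(
    results: Iterable[ArmResult],
    wtp: float,
    frontier: bool = False,
    reference: str = DO_NOTHING,
) -> CEAResult:
    """Build the full deterministic CEA table.

    Rows are sorted ascending by DMFT averted (the comparator first).
    ``ranked_icer`` compares each arm with the previous row; the
    comparator row carries NaN markers. With ``frontier=True`` the
    ``dominated``/``extended_dominated`` flags identify off-frontier arms;
    ranked ICERs are reported for all arms either way.
    """
    rows = rank_by_effectiveness(results)
    names = [r.name for r in rows]
    if reference not in names:
        raise ValueError(f"results must include the {reference!r} comparator")
    ref = next(r for r in rows if r.name == reference)

    strict = _strictly_dominated(rows) if frontier else [False] * len(rows)
    extended = (
        _extended_dominated(rows, strict) if frontier else [False] * len(rows)
    )

    records = []
    prev: Optional[ArmResult] = None
    for r, dom, ext in zip(rows, strict, extended):
        is_ref = r.name == reference
        icer_dn = float("nan")
        ranked = float("nan")
        if not is_ref:
            try:
                icer_dn = icer(
                    r.total_cost, r.dmft_averted, ref.total_cost, ref.dmft_averted
                )
            except UndefinedICERError:
                icer_dn = float("nan")
            if prev is not None:
                try:
                    ranked = icer(
                        r.total_cost, r.dmft_averted,
                        prev.total_cost, prev.dmft_averted,
                    )
                except UndefinedICERError:
                    ranked = float("nan")
        records.append(
            {
                "name": r.name,
                "total_cost": r.total_cost,
                "dmft_averted": r.dmft_averted,
                "average_lifetime_cost": r.average_lifetime_cost,
                "icer_vs_donothing": icer_dn,
                "ranked_icer": ranked,
                "nmb": nmb(r.total_cost, r.dmft_averted, wtp),
                "dominated": dom,
                "extended_dominated": ext,
            }
        )
        prev = r
    return CEAResult(table=pd.DataFrame(records), wtp=wtp)


def optimal_arm(results: Iterable[ArmResult], wtp: float) -> str:
    """Name of the NMB-maximising arm at a threshold (ties: cheaper wins)."""
    rows = list(results)
    return max(
        rows, key=lambda r: (nmb(r.total_cost, r.dmft_averted, wtp), -r.total_cost)
    ).name
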