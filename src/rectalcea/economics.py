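"""Economic evaluation: discounted costs, QALMs, ICER and net monetary benefit.

Effectiveness is measured in quality-adjusted life months (QALMs): each
discounted person-month of state occupancy is weighted by the state utility.
Costs are the same occupancies weighted by per-cycle state costs, plus any
one-time upfront cost charged undiscounted in the first cycle.  Two
strategies are compared by incremental cost, incremental effectiveness, their
ratio (the ICER, in USD per QALM gained) and per-strategy net monetary
benefit NMB = effectiveness x WTP - cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .cohort import CohortTrace, run_cohort
from .parameters import EconomicSettings, StrategyParameters

__all__ = [
    "EconomicOutcome",
    "ComparisonResult",
    "accumulate",
    "evaluate_strategy",
    "compare",
    "net_monetary_benefit",
    "comparison_frame",
]

Dominance = Literal["none", "intervention_dominates", "comparator_dominates"]


@dataclass(frozen=True)
class EconomicOutcome:
    """Discounted per-state and total cost (USD) and effectiveness (QALM)."""

    strategy: str
    cost_dfs: float
    cost_pd: float
    qalm_dfs: float
    qalm_pd: float

    @property
    def cost_total(self) -> float:
        return self.cost_dfs + self.cost_pd

    @property
    def qalm_total(self) -> float:
        return self.qalm_dfs + self.qalm_pd


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental economics of intervention vs comparator.

    ``icer`` is None when the effectiveness difference is zero (undefined
    ratio) and also when one strategy dominates — a negative ratio carries
    no decision information, so dominated pairs are flagged instead.
    """

    intervention: EconomicOutcome
    comparator: EconomicOutcome
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: Dominance
    wtp: float
    nmb_intervention: float
    nmb_comparator: float

    @property
    def nmb_incremental(self) -> float:
        return self.nmb_intervention - self.nmb_comparator


def net_monetary_benefit(effect: float, cost: float, wtp: float) -> float:
    """NMB = effectiveness x WTP - cost, in USD."""
    return effect * wtp - cost


def accumulate(trace: CohortTrace, params: StrategyParameters) -> EconomicOutcome:
    """Turn a cohort trace into discounted state costs and QALMs.

    The trace must have been produced for the same strategy; the upfront
    cost (if any) is added to the DFS-state cost undiscounted.
    """
    if trace.strategy and trace.strategy != params.name:
        raise ValueError(
            f"trace was run for strategy {trace.strategy!r}, not {params.name!r}"
        )
    occ_dfs = trace.occupancy["dfs"]
    occ_pd = trace.occupancy["pd"]
    return EconomicOutcome(
        strategy=params.name,
        cost_dfs=occ_dfs * params.costs.cost_dfs_cycle + params.costs.cost_upfront,
        cost_pd=occ_pd * params.costs.cost_pd_cycle,
        qalm_dfs=occ_dfs * params.utilities.u_dfs,
        qalm_pd=occ_pd * params.utilities.u_pd,
    )


def evaluate_strategy(
    params: StrategyParameters, settings: EconomicSettings
) -> EconomicOutcome:
    """Run the cohort and accumulate economics in one step."""
    return accumulate(run_cohort(params, settings), params)


def compare(
    intervention: EconomicOutcome,
    comparator: EconomicOutcome,
    wtp: float,
) -> ComparisonResult:
    """Incremental comparison (intervention minus comparator) at a given WTP."""
    d_cost = intervention.cost_total - comparator.cost_total
    d_eff = intervention.qalm_total - comparator.qalm_total
    dominance: Dominance = "none"
    if d_cost < 0 and d_eff > 0:
        dominance = "intervention_dominates"
    elif d_cost > 0 and d_eff < 0:
        dominance = "comparator_dominates"
    icer = d_cost / d_eff if d_eff != 0 and dominance == "none" else None
    return ComparisonResult(
        intervention=intervention,
        comparator=comparator,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=icer,
        dominance=dominance,
        wtp=wtp,
        nmb_intervention=net_monetary_benefit(
            intervention.qalm_total, intervention.cost_total, wtp
        ),
        nmb_comparator=net_monetary_benefit(
            comparator.qalm_total, comparator.cost_total, wtp
        ),
    )


def comparison_frame(result: ComparisonResult) -> pd.DataFrame:
    """Tabular export of a comparison: per-state costs and QALMs per
    strategy, totals, increments, ICER and NMB."""
    rows = []
    for outcome in (result.intervention, result.comparator):
        rows.append(
            {
                "strategy": outcome.strategy,
                "cost_dfs": outcome.cost_dfs,
                "cost_pd": outcome.cost_pd,
                "cost_total": outcome.cost_total,
                "qalm_dfs": outcome.qalm_dfs,
                "qalm_pd": outcome.qalm_pd,
                "qalm_total": outcome.qalm_total,
                "nmb": net_monetary_benefit(
                    outcome.qalm_total, outcome.cost_total, result.wtp
                ),
            }
        )
    rows.append(
        {
            "strategy": "incremental",
            "cost_total": result.delta_cost,
            "qalm_total": result.delta_effect,
            "nmb": result.nmb_incremental,
        }
    )
    frame = pd.DataFrame(rows)
    frame["icer"] = [None, None, result.icer]
    frame["dominance"] = [None, None, result.dominance]
    return frame
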