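"""Three-state monthly Markov cohort engine.

The cohort starts entirely in the disease-free survival (DFS) state and each
cycle may move to progressive disease (PD) or death; PD may move to death;
death is absorbing and there is no recovery from PD.  The engine produces the
full membership trace and discounted, optionally half-cycle-corrected state
occupancy in person-months, which the economic layer multiplies by per-cycle
costs and utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import EconomicSettings, StrategyParameters

__all__ = ["CohortTrace", "discount_factor", "run_cohort", "trace_frame"]

STATES = ("dfs", "pd", "dead")


@dataclass(frozen=True)
class CohortTrace:
    """Result of one cohort run.

    ``membership`` has shape (horizon + 1, 3) with columns (dfs, pd, dead);
    row t is the state distribution at the start of cycle t.  ``occupancy``
    maps each living state to its discounted (and, when enabled,
    half-cycle-corrected) person-months.
    """

    membership: np.ndarray
    occupancy: dict[str, float]
    discount: np.ndarray
    settings: EconomicSettings
    strategy: str = ""

    @property
    def dfs(self) -> np.ndarray:
        return self.membership[:, 0]

    @property
    def pd(self) -> np.ndarray:
        return self.membership[:, 1]

    @property
    def dead(self) -> np.ndarray:
        return self.membership[:, 2]


def discount_factor(cycle, settings: EconomicSettings):
    """Per-cycle discount factor (1 + r)^(-t/12), anchored at cycle 0."""
    t = np.asarray(cycle, dtype=float)
    if np.any(t < 0):
        raise ValueError("cycle index must be non-negative")
    out = (1.0 + settings.annual_discount_rate) ** (-t / 12.0)
    return float(out) if out.ndim == 0 else out


def _cycle_weights(n_cycles: int, half_cycle_correction: bool) -> np.ndarray:
    """Trapezoid weights (half at the endpoints) when correction is on;
    start-of-cycle weights (cycles 0..horizon-1) when off."""
    w = np.ones(n_cycles + 1)
    if half_cycle_correction:
        w[0] = w[-1] = 0.5
    else:
        w[-1] = 0.0
    return w


def run_cohort(params: StrategyParameters, settings: EconomicSettings) -> CohortTrace:
    """Run the deterministic cohort trace for one strategy.

    Everyone starts in DFS.  Each cycle applies the constant monthly
    transition probabilities; occupancy per living state is the weighted,
    discounted sum of membership over cycles 0..horizon.
    """
    n = settings.horizon_cycles
    tr = params.transitions
    membership = np.zeros((n + 1, 3))
    membership[0] = (1.0, 0.0, 0.0)
    for t in range(n):
        dfs, pd_, dead = membership[t]
        membership[t + 1, 0] = dfs * tr.p_dfs_stay
        membership[t + 1, 1] = pd_ * (1.0 - tr.p_pd_death) + dfs * tr.p_dfs_pd
        membership[t + 1, 2] = dead + dfs * tr.p_dfs_death + pd_ * tr.p_pd_death
    disc = discount_factor(np.arange(n + 1), settings)
    w = _cycle_weights(n, settings.half_cycle_correction)
    occupancy = {
        "dfs": float(np.sum(membership[:, 0] * disc * w)),
        "pd": float(np.sum(membership[:, 1] * disc * w)),
    }
    return CohortTrace(
        membership=membership,
        occupancy=occupancy,
        discount=disc,
        settings=settings,
        strategy=params.name,
    )


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Trace as a DataFrame with columns cycle,dfs,pd,dead,discount_factor."""
    n = trace.membership.shape[0]
    return pd.DataFrame(
        {
            "cycle": np.arange(n),
            "dfs": trace.dfs,
            "pd": trace.pd,
            "dead": trace.dead,
            "discount_factor": trace.discount,
        }
    )
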