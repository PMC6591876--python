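"""Deterministic and probabilistic sensitivity analyses.

Three tools probe the robustness of the base-case comparison:

* :func:`one_way_tornado` — vary one scalar input at a time by a relative
  range (default +/-20%) and record the incremental net monetary benefit at
  the low and high values; the sorted ranges form the tornado diagram data.
* :func:`run_psa` — probabilistic sensitivity analysis: draw every input
  from an uncertainty distribution each trial (beta for probabilities and
  utilities, gamma for costs, moment-matched so the mean is the base value
  and +/-20% of base spans roughly the central 95% interval), run the model
  per trial and collect (cost, effectiveness) pairs per strategy.  A
  microsimulation mode averages individually simulated patient paths
  instead of the deterministic cohort.
* :func:`ceac` — cost-effectiveness acceptability curves: the fraction of
  PSA trials in which each strategy has the highest net monetary benefit at
  each willingness-to-pay value.

:func:`threshold_pd_cost` performs the threshold search on the shared
progressive-disease per-cycle cost: the value at which the full-model ICER
equals the willingness-to-pay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import _cycle_weights, discount_factor, run_cohort
from .economics import (
    EconomicOutcome,
    accumulate,
    compare,
    evaluate_strategy,
    net_monetary_benefit,
)
from .parameters import EconomicSettings, StrategyParameters

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "one_way_tornado",
    "run_psa",
    "ceac",
    "threshold_pd_cost",
    "threshold_pd_cost_closed_form",
    "simulate_individuals",
    "tornado_frame",
    "ceac_frame",
]

# 95% central interval half-width in standard-deviation units
_Z95 = 1.959963984540054

PSAMode = Literal["cohort", "microsimulation"]

# Scalar inputs varied in sensitivity analyses.  The progressive-disease
# cost is a single externally borrowed parameter applied identically to both
# arms, so its two copies move together; everything else — transition
# probabilities, the DFS per-cycle cost and the state utilities — is an
# arm-specific model input and varies independently, as in a per-branch
# decision-tree parameterization.
_SHARED_PARAMS = ("cost_pd_cycle",)
_ARM_PARAMS = ("p_dfs_pd", "p_dfs_death", "p_pd_death", "cost_dfs_cycle", "u_dfs", "u_pd")
_PROB_LIKE = ("p_dfs_pd", "p_dfs_death", "p_pd_death", "u_dfs", "u_pd")


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram."""

    parameter: str
    low_value: float
    high_value: float
    nmb_low: float
    nmb_high: float

    @property
    def range(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


@dataclass(frozen=True)
class PSAResult:
    """Per-trial (cost, effectiveness) draws for both strategies.

    Arrays have length ``n_trials``; strategies are keyed by name.
    """

    costs: dict[str, np.ndarray]
    effects: dict[str, np.ndarray]
    n_trials: int
    n_individuals: int
    seed: int
    mode: PSAMode
    sampling: str

    @property
    def strategies(self) -> tuple[str, ...]:
        return tuple(self.costs)


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability probabilities per strategy on a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probability: dict[str, np.ndarray]


def _get_scalar(params: StrategyParameters, name: str) -> float:
    for component in (params.transitions, params.costs, params.utilities):
        if hasattr(component, name):
            return getattr(component, name)
    raise KeyError(name)


def _scaled(params: StrategyParameters, name: str, value: float) -> StrategyParameters:
    """Set one scalar, capping probability-like values at 1 and clipping the
    DFS exit-probability sum with a warning when scaling overruns it."""
    if name in _PROB_LIKE:
        value = min(value, 1.0)
    if name == "p_dfs_pd" and value + params.transitions.p_dfs_death > 1.0:
        warnings.warn("scaled p_dfs_pd clipped: DFS exit probabilities exceed 1")
        value = 1.0 - params.transitions.p_dfs_death
    if name == "p_dfs_death" and value + params.transitions.p_dfs_pd > 1.0:
        warnings.warn("scaled p_dfs_death clipped: DFS exit probabilities exceed 1")
        value = 1.0 - params.transitions.p_dfs_pd
    return params.replace(**{name: value})


def one_way_tornado(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    settings: EconomicSettings,
    rel_range: float = 0.20,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis on the incremental net monetary benefit.

    Each scalar input is set to base x (1 - rel_range) and base x
    (1 + rel_range) with everything else fixed, both cohorts re-run, and the
    incremental NMB (intervention minus comparator, at ``settings.wtp``)
    recorded.  Entries are sorted by descending NMB range.
    """
    if not 0.0 <= rel_range < 1.0:
        raise ValueError("rel_range must lie in [0, 1)")

    def inc_nmb(a: StrategyParameters, b: StrategyParameters) -> float:
        res = compare(
            evaluate_strategy(a, settings), evaluate_strategy(b, settings), settings.wtp
        )
        return res.nmb_incremental

    entries: list[TornadoEntry] = []
    for name in _SHARED_PARAMS:
        base = _get_scalar(intervention, name)
        lo, hi = base * (1 - rel_range), base * (1 + rel_range)
        nmb_lo = inc_nmb(_scaled(intervention, name, lo), _scaled(comparator, name, lo))
        nmb_hi = inc_nmb(_scaled(intervention, name, hi), _scaled(comparator, name, hi))
        entries.append(TornadoEntry(name, lo, hi, nmb_lo, nmb_hi))
    for arm, other in ((intervention, comparator), (comparator, intervention)):
        for name in _ARM_PARAMS:
            base = _get_scalar(arm, name)
            lo, hi = base * (1 - rel_range), base * (1 + rel_range)
            label = f"{name}[{arm.name}]"
            if arm is intervention:
                nmb_lo = inc_nmb(_scaled(arm, name, lo), other)
                nmb_hi = inc_nmb(_scaled(arm, name, hi), other)
            else:
                nmb_lo = inc_nmb(other, _scaled(arm, name, lo))
                nmb_hi = inc_nmb(other, _scaled(arm, name, hi))
            entries.append(TornadoEntry(label, lo, hi, nmb_lo, nmb_hi))
    entries.sort(key=lambda e: e.range, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

def _sample_beta(rng: np.ndarray, base: float, rel_range: float, n: int) -> np.ndarray:
    """Beta draws with mean ``base`` and sd chosen so +/-rel_range of base
    approximates the central 95% interval."""
    if base <= 0.0 or rel_range == 0.0:
        return np.full(n, base)
    sd = rel_range * base / _Z95
    var = sd * sd
    var = min(var, 0.99 * base * (1.0 - base))  # beta feasibility bound
    nu = base * (1.0 - base) / var - 1.0
    return rng.beta(base * nu, (1.0 - base) * nu, size=n)


def _sample_gamma(rng, base: float, rel_range: float, n: int) -> np.ndarray:
    if base <= 0.0 or rel_range == 0.0:
        return np.full(n, base)
    sd = rel_range * base / _Z95
    k = (base / sd) ** 2
    return rng.gamma(shape=k, scale=base / k, size=n)


def _sample_uniform(rng, base: float, rel_range: float, n: int) -> np.ndarray:
    if rel_range == 0.0:
        return np.full(n, base)
    return rng.uniform(base * (1 - rel_range), base * (1 + rel_range), size=n)


def _sample_parameter_table(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    rng,
    n_trials: int,
    rel_range: float,
    sampling: str,
) -> dict[str, np.ndarray]:
    """Per-trial draws for every varied parameter, shared ones drawn once."""
    if sampling == "uniform":
        beta = gamma = lambda base, n: _sample_uniform(rng, base, rel_range, n)
    elif sampling == "beta-gamma":
        beta = lambda base, n: _sample_beta(rng, base, rel_range, n)
        gamma = lambda base, n: _sample_gamma(rng, base, rel_range, n)
    else:
        raise ValueError(f"unknown sampling spec {sampling!r}")
    table: dict[str, np.ndarray] = {}
    for name in _SHARED_PARAMS:
        base = _get_scalar(intervention, name)
        draw = gamma if name.startswith("cost") else beta
        table[name] = np.clip(draw(base, n_trials), 0.0, 1.0 if name in _PROB_LIKE else np.inf)
    for arm in (intervention, comparator):
        for name in _ARM_PARAMS:
            base = _get_scalar(arm, name)
            draw = gamma if name.startswith("cost") else beta
            table[f"{name}[{arm.name}]"] = np.clip(
                draw(base, n_trials), 0.0, 1.0 if name in _PROB_LIKE else np.inf
            )
    return table


def _trial_params(
    base: StrategyParameters, table: dict[str, np.ndarray], trial: int
) -> StrategyParameters:
    updates = {}
    for name in _SHARED_PARAMS:
        updates[name] = float(table[name][trial])
    for name in _ARM_PARAMS:
        updates[name] = float(table[f"{name}[{base.name}]"][trial])
    # renormalize if sampled DFS exit probabilities overrun 1
    total = updates["p_dfs_pd"] + updates["p_dfs_death"]
    if total > 1.0:
        updates["p_dfs_pd"] /= total
        updates["p_dfs_death"] /= total
    with warnings.catch_warnings():
        # independent utility draws may cross the base ordering; expected here
        warnings.simplefilter("ignore", UserWarning)
        return base.replace(**updates)


def simulate_individuals(
    params: StrategyParameters,
    settings: EconomicSettings,
    n_individuals: int,
    rng: np.random.Generator,
) -> EconomicOutcome:
    """Microsimulation: average economics over individually simulated paths.

    Simulates ``n_individuals`` patient trajectories through the 3-state
    chain, builds the empirical membership trace, and accumulates discounted
    occupancy exactly as the deterministic cohort does, so the two modes
    agree in expectation.
    """
    n = settings.horizon_cycles
    tr = params.transitions
    state = np.zeros(n_individuals, dtype=np.int8)  # 0 dfs, 1 pd, 2 dead
    membership = np.zeros((n + 1, 3))
    membership[0, 0] = 1.0
    for t in range(n):
        u = rng.random(n_individuals)
        in_dfs = state == 0
        in_pd = state == 1
        to_pd = in_dfs & (u < tr.p_dfs_pd)
        to_death_from_dfs = in_dfs & (u >= tr.p_dfs_pd) & (u < tr.p_dfs_pd + tr.p_dfs_death)
        to_death_from_pd = in_pd & (u < tr.p_pd_death)
        state[to_pd] = 1
        state[to_death_from_dfs | to_death_from_pd] = 2
        counts = np.bincount(state, minlength=3)
        membership[t + 1] = counts / n_individuals
    disc = discount_factor(np.arange(n + 1), settings)
    w = _cycle_weights(n, settings.half_cycle_correction)
    occ_dfs = float(np.sum(membership[:, 0] * disc * w))
    occ_pd = float(np.sum(membership[:, 1] * disc * w))
    return EconomicOutcome(
        strategy=params.name,
        cost_dfs=occ_dfs * params.costs.cost_dfs_cycle + params.costs.cost_upfront,
        cost_pd=occ_pd * params.costs.cost_pd_cycle,
        qalm_dfs=occ_dfs * params.utilities.u_dfs,
        qalm_pd=occ_pd * params.utilities.u_pd,
    )


def run_psa(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    settings: EconomicSettings,
    n_trials: int = 1000,
    n_individuals: int = 10_000,
    seed: int = 0,
    mode: PSAMode = "cohort",
    rel_range: float = 0.20,
    sampling: str = "beta-gamma",
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Per trial every input is drawn from its uncertainty distribution and the
    model evaluated; ``mode='cohort'`` runs the deterministic cohort per
    trial (fast), ``mode='microsimulation'`` averages ``n_individuals``
    simulated patient paths per trial.  Fully reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mode not in ("cohort", "microsimulation"):
        raise ValueError(f"unknown PSA mode {mode!r}")
    rng = np.random.default_rng(seed)
    table = _sample_parameter_table(
        intervention, comparator, rng, n_trials, rel_range, sampling
    )
    costs = {intervention.name: np.empty(n_trials), comparator.name: np.empty(n_trials)}
    effects = {intervention.name: np.empty(n_trials), comparator.name: np.empty(n_trials)}
    for trial in range(n_trials):
        for base in (intervention, comparator):
            params = _trial_params(base, table, trial)
            if mode == "cohort":
                outcome = accumulate(run_cohort(params, settings), params)
            else:
                outcome = simulate_individuals(params, settings, n_individuals, rng)
            costs[base.name][trial] = outcome.cost_total
            effects[base.name][trial] = outcome.qalm_total
    return PSAResult(
        costs=costs,
        effects=effects,
        n_trials=n_trials,
        n_individuals=n_individuals if mode == "microsimulation" else 0,
        seed=seed,
        mode=mode,
        sampling=sampling,
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each willingness-to-pay value, the probability for a strategy is the
    fraction of trials in which it attains the strictly highest net monetary
    benefit; exact ties are split equally.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    names = psa.strategies
    prob = {name: np.zeros(grid.size) for name in names}
    nmb = np.stack(
        [
            psa.effects[name][None, :] * grid[:, None] - psa.costs[name][None, :]
            for name in names
        ]
    )  # (strategy, wtp, trial)
    best = nmb.max(axis=0)
    for i, name in enumerate(names):
        is_best = nmb[i] == best
        n_tied = (nmb == best).sum(axis=0)
        prob[name] = (is_best / n_tied).sum(axis=1) / psa.n_trials
    return CEACCurve(wtp_grid=grid, probability=prob)


# ---------------------------------------------------------------------------
# Threshold analysis on the shared PD-state cost
# ---------------------------------------------------------------------------

def _icer_at_pd_cost(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    settings: EconomicSettings,
    pd_cost: float,
) -> float | None:
    res = compare(
        evaluate_strategy(intervention.replace(cost_pd_cycle=pd_cost), settings),
        evaluate_strategy(comparator.replace(cost_pd_cycle=pd_cost), settings),
        settings.wtp,
    )
    return res.icer


def threshold_pd_cost(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    settings: EconomicSettings,
    bracket: tuple[float, float] = (0.0, 4920.50),
    tol: float = 0.01,
) -> float:
    """Common per-cycle PD cost at which the full-model ICER equals the WTP.

    The PD cost is applied to both arms simultaneously and bisected within
    ``bracket`` until the ICER crosses ``settings.wtp``, to +/-``tol``
    dollars.  Because state occupancies do not depend on costs the ICER is
    linear (hence monotone) in the PD cost; this is verified at the bracket
    ends and a ``ValueError`` raised if the root is not bracketed.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must be an increasing interval")

    def gap(c: float) -> float:
        icer = _icer_at_pd_cost(intervention, comparator, settings, c)
        if icer is None:
            raise ValueError("ICER undefined within the bracket (zero or dominated increment)")
        return icer - settings.wtp

    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValueError(
            f"ICER does not cross the WTP within the bracket "
            f"(gap {g_lo:.2f} at {lo}, {g_hi:.2f} at {hi})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        if g_mid == 0.0:
            return mid
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def threshold_pd_cost_closed_form(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    settings: EconomicSettings,
) -> float:
    """Analytic threshold: solve (dCost_dfs + c * dOcc_pd) / dEffect = WTP for c.

    Valid because PD occupancy does not depend on the PD cost; serves as an
    independent cross-check of the bisection search.
    """
    tr_i = run_cohort(intervention, settings)
    tr_c = run_cohort(comparator, settings)
    d_occ_pd = tr_i.occupancy["pd"] - tr_c.occupancy["pd"]
    if d_occ_pd == 0.0:
        raise ValueError("PD occupancies are identical; threshold undefined")
    d_cost_dfs = (
        tr_i.occupancy["dfs"] * intervention.costs.cost_dfs_cycle
        + intervention.costs.cost_upfront
        - tr_c.occupancy["dfs"] * comparator.costs.cost_dfs_cycle
        - comparator.costs.cost_upfront
    )
    d_eff = (
        tr_i.occupancy["dfs"] * intervention.utilities.u_dfs
        + tr_i.occupancy["pd"] * intervention.utilities.u_pd
        - tr_c.occupancy["dfs"] * comparator.utilities.u_dfs
        - tr_c.occupancy["pd"] * comparator.utilities.u_pd
    )
    return (settings.wtp * d_eff - d_cost_dfs) / d_occ_pd


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Tornado data as a DataFrame (parameter,low,high,nmb_low,nmb_high,range)."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low_value for e in entries],
            "high": [e.high_value for e in entries],
            "nmb_low": [e.nmb_low for e in entries],
            "nmb_high": [e.nmb_high for e in entries],
            "range": [e.range for e in entries],
        }
    )


def ceac_frame(curve: CEACCurve) -> pd.DataFrame:
    """CEAC data as a DataFrame (wtp plus one probability column per strategy)."""
    data = {"wtp": curve.wtp_grid}
    for name, probs in curve.probability.items():
        data[f"p_{name.lower()}"] = probs
    return pd.DataFrame(data)
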