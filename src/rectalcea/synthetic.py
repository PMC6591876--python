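"""Synthetic inputs with known ground truth.

Real calibration inputs are survival points digitized from published
Kaplan-Meier figures.  This module emulates that process — sampling a known
Weibull curve on a monthly or irregular grid and perturbing it with Gaussian
"pixel-reading" noise — so the calibration workflow can be validated against
curves whose true parameters are known.  It also generates random but
internally valid two-arm parameter sets for property-based testing of the
whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import CostSet, StrategyParameters, TransitionSet, UtilitySet
from .survival import DigitizedCurve, WeibullFit, weibull_survival

__all__ = ["SyntheticCurveSpec", "generate_km_points", "generate_parameter_set"]


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for one synthetic digitized survival curve.

    ``noise_sd`` is in survival-fraction units (default 0.01, roughly the
    pixel-reading error of digitizing a printed curve).  ``regular_grid``
    samples at evenly spaced months; otherwise times are sorted uniform
    draws on (0, max_time].
    """

    true_shape: float
    true_scale: float
    n_points: int = 72
    max_time: float = 72.0
    noise_sd: float = 0.01
    seed: int = 0
    regular_grid: bool = True
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.true_shape <= 0 or self.true_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")


def generate_km_points(spec: SyntheticCurveSpec) -> DigitizedCurve:
    """Sample a known Weibull curve and add digitization noise.

    Survival values are perturbed by N(0, noise_sd), clipped to [0, 1] and
    monotone-repaired (running minimum), mirroring what a digitized
    Kaplan-Meier curve looks like.  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.regular_grid:
        times = np.linspace(
            spec.max_time / spec.n_points, spec.max_time, spec.n_points
        )
    else:
        times = np.sort(rng.uniform(0.0, spec.max_time, spec.n_points))
        # enforce strictly increasing times (duplicates are measure-zero but
        # guard anyway)
        times = np.unique(times)
        while times.size < spec.n_points:
            extra = rng.uniform(0.0, spec.max_time, spec.n_points - times.size)
            times = np.unique(np.concatenate([times, extra]))
    fit = WeibullFit(shape=spec.true_shape, scale=spec.true_scale)
    surv = weibull_survival(times, fit)
    if spec.noise_sd > 0:
        surv = surv + rng.normal(0.0, spec.noise_sd, size=surv.shape)
    surv = np.clip(surv, 0.0, 1.0)
    surv = np.minimum.accumulate(surv)
    return DigitizedCurve(tuple(times), tuple(surv), label=spec.label)


_DEFAULT_RANGES = {
    "p_dfs_pd": (0.005, 0.05),
    "p_dfs_death": (0.005, 0.05),
    "p_pd_death": (0.01, 0.15),
    "cost_dfs_cycle": (100.0, 1000.0),
    "cost_pd_cycle": (1000.0, 8000.0),
    "u_dfs": (0.6, 0.95),
    "u_pd": (0.3, 0.7),
}


def generate_parameter_set(
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> tuple[StrategyParameters, StrategyParameters]:
    """Random but internally valid two-arm parameter sets.

    Each scalar is drawn uniformly from its range (defaults span plausible
    oncology decision-model values); DFS exit probabilities are renormalized
    if they sum above 1, and the PD utility is capped at the DFS utility.
    Degenerate ranges (lo == hi) pin parameters exactly, so the published
    inputs are reproducible as a special case.
    """
    rng = np.random.default_rng(seed)
    rr = dict(_DEFAULT_RANGES)
    if ranges:
        rr.update(ranges)
    for key, (lo, hi) in rr.items():
        if lo > hi or lo < 0:
            raise ValueError(f"invalid range for {key!r}: ({lo}, {hi})")

    def draw(key: str) -> float:
        lo, hi = rr[key]
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    arms = []
    for name in ("arm_A", "arm_B"):
        p_pd, p_death = draw("p_dfs_pd"), draw("p_dfs_death")
        total = p_pd + p_death
        if total > 1.0:
            p_pd, p_death = p_pd / total, p_death / total
        u_dfs = draw("u_dfs")
        u_pd = min(draw("u_pd"), u_dfs)
        arms.append(
            StrategyParameters(
                name=name,
                transitions=TransitionSet(p_pd, p_death, draw("p_pd_death")),
                costs=CostSet(draw("cost_dfs_cycle"), draw("cost_pd_cycle")),
                utilities=UtilitySet(u_dfs, u_pd),
            )
        )
    return arms[0], arms[1]
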