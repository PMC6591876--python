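"""Weibull calibration of digitized Kaplan-Meier curves.

Trial survival is published only as Kaplan-Meier figures, so the calibration
workflow starts from digitized (time, survival) points.  A two-parameter
Weibull survival function

    S(t) = exp(-(t / scale) ** shape)

is fitted by least squares on a monthly grid: the digitized step function is
interpolated onto t = 1..fit_horizon months and the sum of squared deviations
between the step curve and the Weibull curve is minimized.  Fitted curves are
then reduced to constant monthly transition probabilities for the cohort
model, either directly (DFS exit) or by calibrating the progressive-disease
mortality so the model's overall survival matches the fitted OS curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
from scipy import optimize

__all__ = [
    "DigitizedCurve",
    "WeibullFit",
    "InsufficientDataError",
    "CalibrationError",
    "weibull_survival",
    "fit_weibull",
    "rate_to_prob",
    "prob_to_rate",
    "monthly_prob_from_fit",
    "solve_pd_death",
    "read_curve",
    "write_curve",
]


class InsufficientDataError(ValueError):
    """Too few digitized points to support a fit."""


class CalibrationError(RuntimeError):
    """The requested calibration target cannot be reached."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized Kaplan-Meier curve: ordered (time in months, survival) points.

    Times must be strictly increasing.  Survival values may carry
    digitization noise; ``monotone_repair`` returns a copy with a running
    minimum applied, restoring the non-increasing shape of a KM curve.
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        surv = tuple(float(s) for s in self.survival)
        if len(times) != len(surv):
            raise ValueError("times and survival must have equal length")
        if any(t < 0 for t in times):
            raise ValueError("times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if surv and not 0.0 <= surv[0] <= 1.0:
            raise ValueError("survival values must lie in [0, 1]")
        if any(not 0.0 <= s <= 1.0 for s in surv):
            raise ValueError("survival values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)

    def __len__(self) -> int:
        return len(self.times)

    def monotone_repair(self) -> "DigitizedCurve":
        """Running-minimum repair of digitization noise."""
        repaired = tuple(np.minimum.accumulate(self.survival))
        return DigitizedCurve(self.times, repaired, self.label)

    def step_interpolate(self, grid: Sequence[float]) -> np.ndarray:
        """KM-style step interpolation onto ``grid`` (last value carried
        forward; survival 1 before the first digitized time)."""
        times = np.asarray(self.times)
        surv = np.asarray(self.survival)
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(times, grid, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
        return out


@dataclass(frozen=True)
class WeibullFit:
    """Fitted two-parameter Weibull survival curve with fit diagnostics."""

    shape: float
    scale: float
    sse: float = 0.0
    grid: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")

    def survival(self, t) -> np.ndarray | float:
        return weibull_survival(t, self)


def weibull_survival(t, fit: WeibullFit):
    """Weibull survival S(t) = exp(-(t/scale)^shape); S(0) = 1.

    Accepts scalars or arrays of times in months; negative times are a
    domain error.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-((arr / fit.scale) ** fit.shape))
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def fit_weibull(
    curve: DigitizedCurve,
    fit_horizon: float = 72.0,
    repair: bool = True,
) -> WeibullFit:
    """Least-squares Weibull fit to a digitized KM curve on a monthly grid.

    The digitized points are (optionally) monotone-repaired, step-interpolated
    onto t = 1..fit_horizon months, and the squared deviation from the Weibull
    curve summed over that grid is minimized.  A small multi-start over shape
    guesses guards against local minima; the scale is started at the time at
    which the digitized survival is nearest exp(-1).

    Raises :class:`InsufficientDataError` with fewer than 3 usable points.
    """
    if repair:
        curve = curve.monotone_repair()
    usable = sum(1 for t in curve.times if t <= fit_horizon)
    if usable < 3:
        raise InsufficientDataError(
            f"need >= 3 digitized points within the fit horizon, got {usable}"
        )
    grid = np.arange(1.0, math.floor(fit_horizon) + 1.0)
    target = curve.step_interpolate(grid)

    def sse(params: np.ndarray) -> float:
        shape, scale = params
        model = np.exp(-((grid / scale) ** shape))
        return float(np.sum((model - target) ** 2))

    # scale guess: time of survival closest to exp(-1)
    surv = np.asarray(curve.survival)
    times = np.asarray(curve.times)
    scale0 = float(times[np.argmin(np.abs(surv - math.exp(-1)))])
    if scale0 <= 0:
        scale0 = max(grid[-1] / 2.0, 1.0)
    bounds = [(1e-3, 20.0), (1e-2, 1e4)]
    best = None
    for shape0 in (0.5, 1.0, 2.0):
        res = optimize.minimize(
            sse,
            x0=np.array([shape0, scale0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise CalibrationError("Weibull fit failed to converge")
    shape, scale = best.x
    shape = float(np.clip(shape, bounds[0][0], bounds[0][1]))
    scale = float(np.clip(scale, bounds[1][0], bounds[1][1]))
    return WeibullFit(shape=shape, scale=scale, sse=float(best.fun), grid=tuple(grid))


def rate_to_prob(rate: float, dt: float = 1.0) -> float:
    """Convert a constant event rate (per month) to a probability over ``dt``
    months: p = 1 - exp(-rate * dt)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return 1.0 - math.exp(-rate * dt)


def prob_to_rate(p: float, dt: float = 1.0) -> float:
    """Inverse of :func:`rate_to_prob`: rate = -ln(1 - p) / dt."""
    if not 0.0 <= p < 1.0:
        raise ValueError("probability must lie in [0, 1); p = 1 implies an infinite rate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -math.log1p(-p) / dt


def monthly_prob_from_fit(fit: WeibullFit, match_horizon: float) -> float:
    """Constant monthly exit probability matching the fitted curve at one horizon.

    Returns q with (1 - q)^h = S(h), i.e. the constant-hazard probability
    that reproduces the fitted survival at ``match_horizon`` months.
    """
    if match_horizon <= 0:
        raise ValueError("match_horizon must be positive")
    s = weibull_survival(match_horizon, fit)
    if s <= 0.0:
        raise CalibrationError("survival at the matching horizon is zero")
    return 1.0 - s ** (1.0 / match_horizon)


def solve_pd_death(
    dfs_transitions: tuple[float, float],
    os_fit: WeibullFit,
    match_horizon: float,
    tol: float = 1e-8,
) -> float:
    """Calibrate the monthly PD→death probability against an overall-survival curve.

    Given the DFS exit probabilities ``(p_dfs_pd, p_dfs_death)``, find the
    constant monthly PD→death probability at which the 3-state model's alive
    fraction at ``match_horizon`` equals the fitted OS curve's survival there.
    The alive fraction is monotone decreasing in the PD mortality, so plain
    bisection on [0, 1] suffices.

    Returns 0 by convention when no one enters PD (``p_dfs_pd == 0``).
    Raises :class:`CalibrationError` when the target is outside the range the
    model can reach.
    """
    p_dfs_pd, p_dfs_death = dfs_transitions
    if not (0.0 <= p_dfs_pd <= 1.0 and 0.0 <= p_dfs_death <= 1.0):
        raise ValueError("DFS transition probabilities must lie in [0, 1]")
    if p_dfs_pd + p_dfs_death > 1.0:
        raise ValueError("DFS exit probabilities sum to more than 1")
    horizon = int(round(match_horizon))
    if horizon < 1:
        raise ValueError("match_horizon must be at least one cycle")
    target = weibull_survival(float(match_horizon), os_fit)

    def alive_at_horizon(p_pd_death: float) -> float:
        dfs, pd = 1.0, 0.0
        for _ in range(horizon):
            dfs, pd = (
                dfs * (1.0 - p_dfs_pd - p_dfs_death),
                pd * (1.0 - p_pd_death) + dfs * p_dfs_pd,
            )
        return dfs + pd

    if p_dfs_pd == 0.0:
        return 0.0
    hi_alive = alive_at_horizon(0.0)  # most optimistic: nobody dies from PD
    lo_alive = alive_at_horizon(1.0)  # most pessimistic
    if not lo_alive - 1e-15 <= target <= hi_alive + 1e-15:
        raise CalibrationError(
            f"target OS {target:.6f} at {horizon} months is outside the "
            f"achievable range [{lo_alive:.6f}, {hi_alive:.6f}]"
        )
    lo, hi = 0.0, 1.0
    while hi - lo > 1e-15:
        mid = 0.5 * (lo + hi)
        if abs(alive_at_horizon(mid) - target) < tol:
            return mid
        if alive_at_horizon(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def read_curve(source: str | TextIO, label: str = "") -> DigitizedCurve:
    """Read a digitized curve from delimited text (header time_months,survival)."""
    import csv

    if isinstance(source, str):
        with open(source, newline="") as fh:
            return read_curve(fh, label=label)
    reader = csv.DictReader(source)
    if reader.fieldnames is None or not {"time_months", "survival"} <= set(reader.fieldnames):
        raise ValueError("curve file must have columns time_months,survival")
    times, surv = [], []
    for row in reader:
        times.append(float(row["time_months"]))
        surv.append(float(row["survival"]))
    # tie-break duplicate digitized times: keep the last reading
    dedup: dict[float, float] = {}
    for t, s in zip(times, surv):
        dedup[t] = s
    items = sorted(dedup.items())
    return DigitizedCurve(
        times=tuple(t for t, _ in items),
        survival=tuple(s for _, s in items),
        label=label,
    )


def write_curve(curve: DigitizedCurve, dest: str | TextIO) -> None:
    """Write a digitized curve as delimited text (header time_months,survival)."""
    if isinstance(dest, str):
        with open(dest, "w", newline="") as fh:
            write_curve(curve, fh)
        return
    dest.write("time_months,survival\n")
    for t, s in zip(curve.times, curve.survival):
        dest.write(f"{t:.10g},{s:.10g}\n")
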