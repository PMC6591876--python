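"""Full-analysis driver: run everything and collect a machine-readable report.

:func:`run_full_analysis` executes the whole pipeline for a two-strategy
configuration — cohort runs, economic comparison, tornado analysis, PSA with
acceptability curves, and the PD-cost threshold search — and returns a
:class:`RunReport` whose tables can be written out as delimited text plus a
YAML summary.  Every number in the report comes from the corresponding
module; the driver does no arithmetic of its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .economics import ComparisonResult, EconomicOutcome, compare, evaluate_strategy
from .parameters import EconomicSettings, StrategyParameters, dump_parameters
from .sensitivity import (
    CEACCurve,
    PSAResult,
    TornadoEntry,
    ceac,
    ceac_frame,
    one_way_tornado,
    run_psa,
    threshold_pd_cost,
    threshold_pd_cost_closed_form,
    tornado_frame,
)

__all__ = ["RunReport", "run_full_analysis", "write_report"]

logger = logging.getLogger("rectalcea")


def _version() -> str:
    try:
        return _pkg_version("rectalcea")
    except PackageNotFoundError:
        return "unknown"


@dataclass(frozen=True)
class RunReport:
    """Everything one full analysis produced, plus provenance for re-running."""

    intervention_outcome: EconomicOutcome
    comparator_outcome: EconomicOutcome
    comparison: ComparisonResult
    tornado: list[TornadoEntry]
    psa: PSAResult
    ceac_curve: CEACCurve
    threshold_pd: float
    threshold_pd_closed_form: float
    config_yaml: str
    config_hash: str
    seed: int
    version: str


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage=%s status=start", name)
            return self

        def __exit__(self, *exc):
            elapsed = time.perf_counter() - self.t0
            logger.info("stage=%s status=done elapsed=%.3fs", name, elapsed)
            return False

    return _Timer()


def run_full_analysis(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    settings: EconomicSettings,
    seed: int = 0,
    n_trials: int = 1000,
    n_individuals: int = 10_000,
    psa_mode: str = "cohort",
    rel_range: float = 0.20,
    wtp_grid: np.ndarray | None = None,
    threshold_bracket: tuple[float, float] | None = None,
) -> RunReport:
    """Run cohorts, comparison, tornado, PSA + CEAC and threshold search.

    ``wtp_grid`` defaults to 0..3 x WTP in 100 steps.  The threshold bracket
    defaults to [0, base PD cost].  Stage errors propagate annotated with the
    stage name; each stage is logged to the package logger with timing.
    """
    config_yaml = dump_parameters(intervention, comparator, settings)
    config_hash = hashlib.sha256(config_yaml.encode()).hexdigest()[:16]
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 3.0 * settings.wtp, 100)
    if threshold_bracket is None:
        threshold_bracket = (0.0, intervention.costs.cost_pd_cycle)

    stages: dict[str, object] = {}
    try:
        stage = "cohort"
        with _stage(stage):
            out_i = evaluate_strategy(intervention, settings)
            out_c = evaluate_strategy(comparator, settings)
        stage = "comparison"
        with _stage(stage):
            comparison = compare(out_i, out_c, settings.wtp)
        stage = "tornado"
        with _stage(stage):
            tornado = one_way_tornado(intervention, comparator, settings, rel_range)
        stage = "psa"
        with _stage(stage):
            psa = run_psa(
                intervention,
                comparator,
                settings,
                n_trials=n_trials,
                n_individuals=n_individuals,
                seed=seed,
                mode=psa_mode,  # type: ignore[arg-type]
                rel_range=rel_range,
            )
        stage = "ceac"
        with _stage(stage):
            curve = ceac(psa, wtp_grid)
        stage = "threshold"
        with _stage(stage):
            try:
                thr = threshold_pd_cost(
                    intervention, comparator, settings, threshold_bracket
                )
                thr_cf = threshold_pd_cost_closed_form(intervention, comparator, settings)
            except ValueError as exc:
                logger.warning("stage=threshold not-found: %s", exc)
                thr = thr_cf = float("nan")
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return RunReport(
        intervention_outcome=out_i,
        comparator_outcome=out_c,
        comparison=comparison,
        tornado=tornado,
        psa=psa,
        ceac_curve=curve,
        threshold_pd=thr,
        threshold_pd_closed_form=thr_cf,
        config_yaml=config_yaml,
        config_hash=config_hash,
        seed=seed,
        version=_version(),
    )


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Write all report tables as delimited text plus a YAML summary.

    Returns the mapping of artifact name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    from .economics import comparison_frame

    paths["comparison"] = out / "comparison.csv"
    comparison_frame(report.comparison).to_csv(paths["comparison"], index=False)

    paths["tornado"] = out / "tornado.csv"
    tornado_frame(report.tornado).to_csv(paths["tornado"], index=False)

    paths["ceac"] = out / "ceac.csv"
    ceac_frame(report.ceac_curve).to_csv(paths["ceac"], index=False)

    paths["psa_trials"] = out / "psa_trials.csv"
    psa_df = pd.DataFrame(
        {
            **{f"cost_{k.lower()}": v for k, v in report.psa.costs.items()},
            **{f"qalm_{k.lower()}": v for k, v in report.psa.effects.items()},
        }
    )
    psa_df.to_csv(paths["psa_trials"], index=False)

    paths["config"] = out / "config.yaml"
    paths["config"].write_text(report.config_yaml)

    summary = {
        "version": report.version,
        "seed": report.seed,
        "config_hash": report.config_hash,
        "strategies": {
            o.strategy: {
                "cost_dfs": round(o.cost_dfs, 2),
                "cost_pd": round(o.cost_pd, 2),
                "cost_total": round(o.cost_total, 2),
                "qalm_dfs": round(o.qalm_dfs, 4),
                "qalm_pd": round(o.qalm_pd, 4),
                "qalm_total": round(o.qalm_total, 4),
            }
            for o in (report.intervention_outcome, report.comparator_outcome)
        },
        "incremental": {
            "delta_cost": round(report.comparison.delta_cost, 2),
            "delta_effect": round(report.comparison.delta_effect, 4),
            "icer": None if report.comparison.icer is None else round(report.comparison.icer, 2),
            "dominance": report.comparison.dominance,
            "nmb_incremental": round(report.comparison.nmb_incremental, 2),
        },
        "threshold_pd_cost": None
        if report.threshold_pd != report.threshold_pd
        else round(report.threshold_pd, 2),
        "threshold_pd_cost_closed_form": None
        if report.threshold_pd_closed_form != report.threshold_pd_closed_form
        else round(report.threshold_pd_closed_form, 2),
        "psa": {
            "mode": report.psa.mode,
            "n_trials": report.psa.n_trials,
            "n_individuals": report.psa.n_individuals,
            "sampling": report.psa.sampling,
        },
    }
    paths["summary"] = out / "summary.yaml"
    paths["summary"].write_text(yaml.safe_dump(summary, sort_keys=False))
    return paths
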