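"""Model inputs: transition probabilities, costs, utilities and run settings.

The decision model compares two preoperative strategies for locally advanced
resectable rectal cancer:

* ``SCRT`` — short-course radiotherapy (5 x 5 Gy) followed by consolidation
  chemotherapy (FOLFOX4) and surgery;
* ``LCCRT`` — long-course chemoradiotherapy (28 x 1.8 Gy with oxaliplatin and
  bolus fluorouracil) and delayed surgery.

Each strategy is described by a :class:`StrategyParameters` bundle: constant
monthly transition probabilities between the three health states (disease-free
survival, progressive disease, death), per-cycle state costs in 2018 USD, and
state utilities.  Global run settings (cycle length, horizon, discount rate,
willingness-to-pay) live in :class:`EconomicSettings`.

Canonical published inputs ship as named fixtures, retrievable with
:func:`load_fixture`.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import yaml

__all__ = [
    "EconomicSettings",
    "TransitionSet",
    "CostSet",
    "UtilitySet",
    "StrategyParameters",
    "CostLineItem",
    "ConfigurationError",
    "ValidationError",
    "load_parameters",
    "dump_parameters",
    "load_fixture",
    "fixture_names",
    "cost_line_items",
    "sum_cost_items",
    "read_cost_items",
]


class ConfigurationError(ValueError):
    """A config source is missing a required key or cannot be parsed."""


class ValidationError(ValueError):
    """A parameter value violates its admissible range."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if value < 0.0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class EconomicSettings:
    """Global run settings for the cohort model and economic evaluation.

    Parameters
    ----------
    cycle_length_months:
        Markov cycle length in months.  The model is formulated for monthly
        cycles; only 1 is supported.
    horizon_cycles:
        Number of cycles simulated.  Default 120 (a 10-year horizon).
    annual_discount_rate:
        Annual discount rate applied to both costs and effectiveness,
        compounded per cycle as ``(1 + r)^(-t/12)``.  Default 0.03.
    wtp:
        Willingness-to-pay threshold in USD per quality-adjusted life month
        (QALM).  Default 2370.47, three times the 2017 Chinese per-capita
        monthly GDP figure of $790.
    half_cycle_correction:
        If True (default), state occupancy is accumulated with trapezoid
        weights (half weight at cycle 0 and at the horizon), approximating
        mid-cycle transitions.
    """

    cycle_length_months: float = 1.0
    horizon_cycles: int = 120
    annual_discount_rate: float = 0.03
    wtp: float = 2370.47
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.cycle_length_months != 1.0:
            raise ValidationError("only a 1-month cycle length is supported")
        if int(self.horizon_cycles) < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        object.__setattr__(self, "horizon_cycles", int(self.horizon_cycles))
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError("annual_discount_rate must lie in [0, 1)")
        if self.wtp <= 0.0:
            raise ValidationError("wtp must be positive")


@dataclass(frozen=True)
class TransitionSet:
    """Constant monthly transition probabilities of the 3-state model.

    Death is absorbing and there is no recovery from progression, so the
    only free transitions are DFS→PD, DFS→death and PD→death.
    """

    p_dfs_pd: float
    p_dfs_death: float
    p_pd_death: float

    def __post_init__(self) -> None:
        for name in ("p_dfs_pd", "p_dfs_death", "p_pd_death"):
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))
        if self.p_dfs_pd + self.p_dfs_death > 1.0 + 1e-12:
            raise ValidationError(
                "p_dfs_pd + p_dfs_death must not exceed 1, got "
                f"{self.p_dfs_pd + self.p_dfs_death!r}"
            )

    @property
    def p_dfs_stay(self) -> float:
        return 1.0 - self.p_dfs_pd - self.p_dfs_death


@dataclass(frozen=True)
class CostSet:
    """Per-cycle state costs in USD, plus an optional one-time upfront cost.

    ``cost_upfront`` is charged once in the first cycle (undiscounted); it
    defaults to 0 because the published per-cycle DFS costs already absorb
    the treatment-phase spending.
    """

    cost_dfs_cycle: float
    cost_pd_cycle: float
    cost_upfront: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cost_dfs_cycle", "cost_pd_cycle", "cost_upfront"):
            object.__setattr__(self, name, _check_nonneg(name, getattr(self, name)))


@dataclass(frozen=True)
class UtilitySet:
    """Preference weights per month of life in each state (death fixed at 0)."""

    u_dfs: float
    u_pd: float
    u_death: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_dfs", "u_pd", "u_death"):
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))
        if self.u_death != 0.0:
            raise ValidationError("u_death is fixed at 0")
        if not self.u_pd <= self.u_dfs:
            warnings.warn(
                "utility ordering u_pd <= u_dfs violated "
                f"(u_pd={self.u_pd}, u_dfs={self.u_dfs})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StrategyParameters:
    """Complete model inputs for one treatment strategy (arm)."""

    name: str
    transitions: TransitionSet
    costs: CostSet
    utilities: UtilitySet

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("strategy name must be non-empty")

    def replace(self, **updates) -> "StrategyParameters":
        """Return a copy with nested fields updated.

        Accepts the flat scalar names used throughout the sensitivity
        analysis (``p_dfs_pd``, ``cost_pd_cycle``, ``u_dfs``, ...), mapped
        onto the right nested component.
        """
        trans = dataclasses.asdict(self.transitions)
        costs = dataclasses.asdict(self.costs)
        utils = dataclasses.asdict(self.utilities)
        name = self.name
        for key, value in updates.items():
            if key == "name":
                name = value
            elif key in trans:
                trans[key] = value
            elif key in costs:
                costs[key] = value
            elif key in utils:
                utils[key] = value
            else:
                raise KeyError(f"unknown parameter {key!r}")
        return StrategyParameters(
            name=name,
            transitions=TransitionSet(**trans),
            costs=CostSet(**costs),
            utilities=UtilitySet(**utils),
        )


@dataclass(frozen=True)
class CostLineItem:
    """One line of the per-patient resource-use cost table."""

    CATEGORIES = (
        "radiotherapy",
        "drug",
        "hospitalization",
        "surgery",
        "adverse_event",
        "follow_up",
    )

    category: str
    description: str
    amount: float
    arm: str

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValidationError(
                f"unknown cost category {self.category!r}; "
                f"expected one of {self.CATEGORIES}"
            )
        object.__setattr__(self, "amount", _check_nonneg("amount", self.amount))


# ---------------------------------------------------------------------------
# Bundled fixtures: the published model inputs.
# ---------------------------------------------------------------------------

_SETTINGS_DEFAULTS = EconomicSettings()

# Published per-arm inputs. Utilities 0.84 (DFS) and 0.6 (PD) are the
# narrative values, each anchored to published utility studies; the tabulated
# alternative set (0.65/0.56 DFS, 0.47 PD) is arithmetically inconsistent
# with the printed results and kept as the *_table_utilities variants only.
_FIXTURES: dict[str, dict] = {
    "table1_scrt": dict(
        name="SCRT",
        transitions=dict(p_dfs_pd=0.0204, p_dfs_death=0.0148, p_pd_death=0.0348),
        costs=dict(cost_dfs_cycle=444.85, cost_pd_cycle=4920.50, cost_upfront=0.0),
        utilities=dict(u_dfs=0.84, u_pd=0.6),
    ),
    "table1_lccrt": dict(
        name="LCCRT",
        transitions=dict(p_dfs_pd=0.0244, p_dfs_death=0.0148, p_pd_death=0.1020),
        costs=dict(cost_dfs_cycle=461.34, cost_pd_cycle=4920.50, cost_upfront=0.0),
        utilities=dict(u_dfs=0.84, u_pd=0.6),
    ),
    "table1_scrt_table_utilities": dict(
        name="SCRT",
        transitions=dict(p_dfs_pd=0.0204, p_dfs_death=0.0148, p_pd_death=0.0348),
        costs=dict(cost_dfs_cycle=444.85, cost_pd_cycle=4920.50, cost_upfront=0.0),
        utilities=dict(u_dfs=0.65, u_pd=0.47),
    ),
    "table1_lccrt_table_utilities": dict(
        name="LCCRT",
        transitions=dict(p_dfs_pd=0.0244, p_dfs_death=0.0148, p_pd_death=0.1020),
        costs=dict(cost_dfs_cycle=461.34, cost_pd_cycle=4920.50, cost_upfront=0.0),
        utilities=dict(u_dfs=0.56, u_pd=0.47),
    ),
}

# Reported 3-year survival fractions from the underlying randomized trial
# (NCT00833131), used by the survival-calibration workflow as anchor points.
TRIAL_SURVIVAL_3Y = {
    "SCRT": {"dfs": 0.53, "os": 0.73},
    "LCCRT": {"dfs": 0.52, "os": 0.65},
}

# Per-patient resource-use line items (2018 USD). These document how the
# treatment-phase spending was itemized; they are reference data and are NOT
# inputs to the Markov model (the per-cycle DFS costs above are).
_COST_ITEMS: list[CostLineItem] = [
    CostLineItem("radiotherapy", "physician consultation", 14.7, "SCRT"),
    CostLineItem("radiotherapy", "physician consultation", 14.7, "LCCRT"),
    CostLineItem("radiotherapy", "CT simulation", 470.0, "SCRT"),
    CostLineItem("radiotherapy", "CT simulation", 470.0, "LCCRT"),
    CostLineItem("radiotherapy", "CT simulation surcharge", 5.3, "SCRT"),
    CostLineItem("radiotherapy", "CT simulation surcharge", 5.3, "LCCRT"),
    CostLineItem("radiotherapy", "physics planning", 177.0, "SCRT"),
    CostLineItem("radiotherapy", "physics planning", 177.0, "LCCRT"),
    CostLineItem("radiotherapy", "treatment and positioning (5 fractions)", 3032.0, "SCRT"),
    CostLineItem("radiotherapy", "treatment and positioning (28 fractions)", 4928.0, "LCCRT"),
    CostLineItem("drug", "chemotherapy, DFS state per month", 39.31, "SCRT"),
    CostLineItem("drug", "chemotherapy, DFS state per month", 38.16, "LCCRT"),
    CostLineItem("drug", "chemotherapy, PD state per month", 79.33, "SCRT"),
    CostLineItem("drug", "chemotherapy, PD state per month", 57.95, "LCCRT"),
    CostLineItem("drug", "total drug cost per patient", 7064.01, "SCRT"),
    CostLineItem("drug", "total drug cost per patient", 5670.94, "LCCRT"),
    CostLineItem("hospitalization", "nursing care per day", 52.0, "SCRT"),
    CostLineItem("hospitalization", "nursing care per day", 52.0, "LCCRT"),
    CostLineItem("surgery", "resection", 2963.97, "SCRT"),
    CostLineItem("surgery", "resection", 2645.13, "LCCRT"),
    CostLineItem("adverse_event", "perioperative adverse events", 6.12, "SCRT"),
    CostLineItem("adverse_event", "perioperative adverse events", 5.49, "LCCRT"),
    CostLineItem("follow_up", "baseline surveillance", 396.25, "SCRT"),
    CostLineItem("follow_up", "baseline surveillance", 330.04, "LCCRT"),
    CostLineItem("follow_up", "scheduled follow-up", 3357.58, "SCRT"),
    CostLineItem("follow_up", "scheduled follow-up", 3357.58, "LCCRT"),
]


def fixture_names() -> tuple[str, ...]:
    """Names accepted by :func:`load_fixture`."""
    return tuple(_FIXTURES)


def load_fixture(name: str) -> StrategyParameters:
    """Return one bundled published parameter set by name.

    ``table1_scrt`` and ``table1_lccrt`` are the canonical inputs; the
    ``*_table_utilities`` variants carry the alternative utility values
    printed in the source's parameter table.
    """
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}"
        ) from None
    return _strategy_from_mapping(spec)


def cost_line_items() -> list[CostLineItem]:
    """The bundled per-patient resource-use cost table (reference only)."""
    return list(_COST_ITEMS)


def sum_cost_items(
    items: Iterable[CostLineItem],
    arm: str,
    categories: Iterable[str] | None = None,
) -> float:
    """Sum line-item amounts for one arm, optionally restricted by category.

    Raises ``KeyError`` if ``arm`` matches no item at all (guarding against
    typos); an empty *category* selection within a known arm returns 0.
    """
    items = list(items)
    arm_items = [it for it in items if it.arm == arm]
    if items and not arm_items:
        known = sorted({it.arm for it in items})
        raise KeyError(f"unknown arm {arm!r}; known arms: {known}")
    if categories is not None:
        wanted = set(categories)
        arm_items = [it for it in arm_items if it.category in wanted]
    return float(sum(it.amount for it in arm_items))


def read_cost_items(source: str | TextIO) -> list[CostLineItem]:
    """Read cost line items from delimited text (header category,description,amount,arm)."""
    import csv

    if isinstance(source, str):
        with open(source, newline="") as fh:
            return read_cost_items(fh)
    reader = csv.DictReader(source)
    required = {"category", "description", "amount", "arm"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ConfigurationError(
            f"cost item table must have columns {sorted(required)}"
        )
    return [
        CostLineItem(
            category=row["category"],
            description=row["description"],
            amount=float(row["amount"]),
            arm=row["arm"],
        )
        for row in reader
    ]


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def _require(mapping: Mapping, key: str, context: str) -> object:
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ConfigurationError(f"missing required key {key!r} in {context}") from None


def _strategy_from_mapping(spec: Mapping) -> StrategyParameters:
    trans = _require(spec, "transitions", "strategy")
    costs = _require(spec, "costs", "strategy")
    utils = _require(spec, "utilities", "strategy")
    return StrategyParameters(
        name=str(_require(spec, "name", "strategy")),
        transitions=TransitionSet(
            p_dfs_pd=_require(trans, "p_dfs_pd", "transitions"),
            p_dfs_death=_require(trans, "p_dfs_death", "transitions"),
            p_pd_death=_require(trans, "p_pd_death", "transitions"),
        ),
        costs=CostSet(
            cost_dfs_cycle=_require(costs, "cost_dfs_cycle", "costs"),
            cost_pd_cycle=_require(costs, "cost_pd_cycle", "costs"),
            cost_upfront=costs.get("cost_upfront", 0.0),
        ),
        utilities=UtilitySet(
            u_dfs=_require(utils, "u_dfs", "utilities"),
            u_pd=_require(utils, "u_pd", "utilities"),
        ),
    )


def _settings_from_mapping(spec: Mapping | None) -> EconomicSettings:
    spec = spec or {}
    kwargs = {}
    for fld in dataclasses.fields(EconomicSettings):
        if fld.name in spec:
            kwargs[fld.name] = spec[fld.name]
    return EconomicSettings(**kwargs)


def load_parameters(
    source: str | TextIO | Mapping,
) -> tuple[StrategyParameters, StrategyParameters, EconomicSettings]:
    """Load a two-strategy configuration plus settings from YAML.

    The document must contain ``intervention`` and ``comparator`` strategy
    sections (each with ``name``, ``transitions``, ``costs``, ``utilities``);
    a ``settings`` section is optional and defaults apply for omitted fields.
    A strategy section given as a plain string is resolved as a bundled
    fixture name.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = source if isinstance(source, str) else source.read()
        if isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
            with open(source) as fh:
                text = fh.read()
        try:
            doc = yaml.safe_load(io.StringIO(text))
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigurationError("config must be a mapping")

    def resolve(section: object, label: str) -> StrategyParameters:
        if isinstance(section, str):
            return load_fixture(section)
        if not isinstance(section, Mapping):
            raise ConfigurationError(f"{label} must be a mapping or fixture name")
        return _strategy_from_mapping(section)

    intervention = resolve(_require(doc, "intervention", "config"), "intervention")
    comparator = resolve(_require(doc, "comparator", "config"), "comparator")
    settings = _settings_from_mapping(doc.get("settings"))
    return intervention, comparator, settings


def dump_parameters(
    intervention: StrategyParameters,
    comparator: StrategyParameters,
    settings: EconomicSettings | None = None,
) -> str:
    """Serialize a two-strategy configuration to YAML (round-trips with
    :func:`load_parameters`)."""
    doc = {
        "intervention": dataclasses.asdict(intervention),
        "comparator": dataclasses.asdict(comparator),
        "settings": dataclasses.asdict(settings or _SETTINGS_DEFAULTS),
    }
    return yaml.safe_dump(doc, sort_keys=False)
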