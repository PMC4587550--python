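"""Budget impact of scaling the insured maternal-care package state-wide.

The projection follows the payer formula

    incremental annual cost =
        population in need x per-woman program cost x coverage
        - current annual expenditure on ANC and EOC

applied per calendar year over a five-year horizon, with the population
in need growing at the rate of natural increase and any pre-2012 unit
costs inflated at the historical average rate for Nigeria (12.33%/year).
Per-woman program cost is derived from the same cohort engine and cost
assumptions as the primary analysis (including the above-service
mark-up); cost-sharing revenue is excluded.  The demographic inputs
(population in need, current expenditure, state health expenditure) are
not part of the published input table and default to documented
placeholders; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .accounting import compute_cost
from .parameters import ModelConfig, ParameterDraw, ParameterError, ScenarioConfig
from .pathway import run_cohort

__all__ = [
    "NIGERIA_INFLATION_RATE",
    "PopulationProjection",
    "BudgetProjection",
    "inflate",
    "per_woman_cost",
    "annual_scaleup_cost",
    "project_budget",
]

NIGERIA_INFLATION_RATE = 0.1233  # average 1996-2014


def inflate(cost: float, from_year: int, to_year: int,
            rate: float = NIGERIA_INFLATION_RATE) -> float:
    """Compound-inflate ``cost`` from one price year to another."""
    if to_year < from_year:
        raise ParameterError("years must be ordered")
    return cost * (1.0 + rate) ** (to_year - from_year)


@dataclass(frozen=True)
class PopulationProjection:
    """Women in need of maternal care per calendar year."""

    base_year_population_in_need: float
    growth_rate: float
    years: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.base_year_population_in_need <= 0:
            raise ParameterError("population in need must be positive")

    def population(self, year: int) -> float:
        offset = year - self.years[0]
        return self.base_year_population_in_need * (1.0 + self.growth_rate) ** offset


@dataclass
class BudgetProjection:
    """Per-year, per-coverage incremental cost of state-wide scale-up."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: year, coverage, gross_program_cost, current_expenditure,
    # incremental_cost, relative_increase


def per_woman_cost(
    draw: ParameterDraw, scenario: ScenarioConfig, cohort_size: float = 10_000
) -> float:
    """Expected annual provider cost per woman in need under a scenario,
    from the same cohort engine as the primary analysis."""
    cohort = run_cohort(draw, scenario, cohort_size)
    return compute_cost(cohort, draw, scenario).total_cost / cohort_size


def annual_scaleup_cost(
    pop: PopulationProjection,
    unit_cost_per_woman: float,
    coverage: float,
    current_expenditure: float,
    state_health_expenditure: float | None = None,
) -> BudgetProjection:
    """Incremental annual cost of covering ``coverage`` of the population
    in need at ``unit_cost_per_woman``, above current spending."""
    if not 0.0 <= coverage <= 1.0:
        raise ParameterError("coverage must lie in [0, 1]")
    if current_expenditure < 0:
        raise ParameterError("current expenditure must be non-negative")
    rows = []
    for year in pop.years:
        women = pop.population(year)
        gross = women * coverage * unit_cost_per_woman
        incremental = gross - current_expenditure * (
            women / pop.base_year_population_in_need)
        rows.append({
            "year": year,
            "coverage": coverage,
            "gross_program_cost": gross,
            "current_expenditure": current_expenditure
            * (women / pop.base_year_population_in_need),
            "incremental_cost": incremental,
            "relative_increase": (
                incremental / state_health_expenditure
                if state_health_expenditure else float("nan")),
        })
    return BudgetProjection(rows=pd.DataFrame(rows))


def project_budget(
    config: ModelConfig,
    pop: PopulationProjection,
    coverages: tuple[float, ...] = (0.6, 0.8, 1.0),
    current_utilization: float = 0.5,
    state_health_expenditure: float | None = None,
    base: str = "soc",
    intervention: str = "kshi",
) -> BudgetProjection:
    """Full scale-up projection at parameter point estimates.

    Current expenditure on ANC and EOC is derived as the population in need
    times the current utilization share times the standard-of-care
    per-woman cost, so the increment is zero when coverage, utilization and
    unit costs all coincide.
    """
    params = config.merged_params(base, intervention)
    draw = params.point_draw()
    unit_kshi = per_woman_cost(draw, config.scenarios[intervention],
                               params.cohort_size)
    unit_soc = per_woman_cost(draw, config.scenarios[base], params.cohort_size)
    current = pop.base_year_population_in_need * current_utilization * unit_soc
    frames = [
        annual_scaleup_cost(pop, unit_kshi, cov, current,
                            state_health_expenditure).rows
        for cov in coverages
    ]
    return BudgetProjection(rows=pd.concat(frames, ignore_index=True))
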