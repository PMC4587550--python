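"""DALY and provider-cost accounting for a resolved cohort.

Health accounting supports two modes:

``loss``
    Total DALYs incurred: years of life lost to maternal deaths plus years
    lived with disability from sequelae.  Lower is better; differences
    between scenarios are DALYs averted.

``ledger`` (default)
    Each woman is credited a fixed number of discounted healthy life-years
    and the cohort losses are subtracted, reproducing the scale of the
    published per-scenario DALY totals.  Higher is better; differences are
    again DALYs averted, so the two modes yield identical incremental
    results up to sign convention.

The per-death DALY value is a discounted remaining-life-expectancy figure
evaluated at 3%/year; when an analysis varies the discount rate the
long-horizon weights (death, extended hypertensive morbidity and the
ledger baseline) are rescaled through :func:`discounted_years`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ParameterDraw, ParameterError, ScenarioConfig
from .pathway import CohortTable

__all__ = [
    "HealthSummary",
    "CostSummary",
    "discounted_years",
    "compute_health",
    "compute_cost",
]

REFERENCE_DISCOUNT_RATE = 0.03


def discounted_years(horizon: float, rate: float) -> float:
    """Continuously discounted year-equivalents over ``horizon`` years.

    Closed form (1 - exp(-rate * horizon)) / rate; the zero-rate limit is
    the horizon itself.
    """
    if horizon < 0 or rate < 0:
        raise ParameterError("horizon and discount rate must be non-negative")
    if rate == 0.0:
        return float(horizon)
    return (1.0 - math.exp(-rate * horizon)) / rate


def _rate_rescale(draw: ParameterDraw, value: float) -> float:
    """Rescale a 3%-discounted long-horizon DALY weight to the draw's rate."""
    rate = draw.resolve("discount_rate")
    if rate == REFERENCE_DISCOUNT_RATE:
        return value
    ref_death = 23.43  # per-death weight at the reference 3%/year
    horizon = -math.log(1.0 - REFERENCE_DISCOUNT_RATE * ref_death) / REFERENCE_DISCOUNT_RATE
    return value * discounted_years(horizon, rate) / ref_death


@dataclass(frozen=True)
class HealthSummary:
    """Scenario-level DALY account."""

    yll: float
    yld_by_sequela: dict[str, float]
    total_effect: float
    baseline_healthy_life_per_woman: float
    mode: str = "ledger"

    @property
    def yld(self) -> float:
        return sum(self.yld_by_sequela.values())

    @property
    def loss(self) -> float:
        return self.yll + self.yld

    @property
    def gain(self) -> float:
        """Health on a higher-is-better scale regardless of mode."""
        return self.total_effect if self.mode == "ledger" else -self.total_effect


@dataclass(frozen=True)
class CostSummary:
    """Scenario-level provider-perspective costs (US$ 2012)."""

    anc_cost: float
    uncomplicated_delivery_cost: float
    complicated_delivery_cost: float
    fistula_treatment_cost: float
    anaemia_treatment_cost: float
    above_service_cost: float

    @property
    def total_cost(self) -> float:
        return (self.anc_cost + self.uncomplicated_delivery_cost
                + self.complicated_delivery_cost + self.fistula_treatment_cost
                + self.anaemia_treatment_cost + self.above_service_cost)

    def as_dict(self) -> dict[str, float]:
        return {
            "anc_cost": self.anc_cost,
            "uncomplicated_delivery_cost": self.uncomplicated_delivery_cost,
            "complicated_delivery_cost": self.complicated_delivery_cost,
            "fistula_treatment_cost": self.fistula_treatment_cost,
            "anaemia_treatment_cost": self.anaemia_treatment_cost,
            "above_service_cost": self.above_service_cost,
            "total_cost": self.total_cost,
        }


def compute_health(
    cohort: CohortTable, draw: ParameterDraw, mode: str = "ledger"
) -> HealthSummary:
    """DALY account for a resolved cohort under the given accounting mode."""
    if mode not in ("ledger", "loss"):
        raise ParameterError(f"unknown health accounting mode {mode!r}")
    totals = cohort.totals()
    yll = totals["deaths"] * _rate_rescale(draw, draw.resolve("daly_death"))
    yld = {
        "anaemia": totals["anaemia"] * draw.resolve("daly_anaemia"),
        "infertility": totals["infertility"] * draw.resolve("daly_infertility"),
        "fistula": totals["fistula"] * draw.resolve("daly_fistula"),
        "extended_htd": totals["htd_survivors"]
        * _rate_rescale(draw, draw.resolve("daly_extended_htd")),
    }
    baseline = _rate_rescale(draw, draw.resolve("baseline_healthy_life"))
    loss = yll + sum(yld.values())
    if mode == "ledger":
        total_effect = cohort.cohort_size * baseline - loss
    else:
        total_effect = loss
    return HealthSummary(
        yll=yll, yld_by_sequela=yld, total_effect=total_effect,
        baseline_healthy_life_per_woman=baseline, mode=mode,
    )


def compute_cost(
    cohort: CohortTable, draw: ParameterDraw, scenario: ScenarioConfig
) -> CostSummary:
    """Provider-perspective cost account for a resolved cohort.

    Costing rules: ANC attendees incur the per-pregnancy ANC cost; facility
    deliveries without complications incur the uncomplicated unit cost;
    complicated deliveries incur the complicated (EOC) package when EOC is
    accessed, the uncomplicated unit cost when delivered in a facility
    without EOC, and nothing at home without EOC; home deliveries without
    complications are uncosted (no provider contact).  Sequela treatment
    costs follow fistula and anaemia cases.  The above-service per-enrolee
    mark-up applies to every cohort member when the scenario is insured.
    """
    for name in ("cost_anc", "cost_delivery_uncomplicated",
                 "cost_delivery_complicated", "cost_fistula_treatment",
                 "cost_anaemia_treatment", "above_service_cost"):
        if scenario.value(draw, name) < 0:
            raise ParameterError(f"negative unit cost for {name}")

    c_anc = scenario.value(draw, "cost_anc")
    c_unc = scenario.value(draw, "cost_delivery_uncomplicated")
    c_comp = scenario.value(draw, "cost_delivery_complicated")

    anc_cost = cohort.anc_attendees() * c_anc
    unc_cost = 0.0
    comp_cost = 0.0
    for row in cohort.rows:
        complicated = row.complications.complicated
        if row.stratum.eoc:
            comp_cost += complicated * c_comp
        elif row.stratum.facility:
            comp_cost += complicated * c_unc
        if row.stratum.facility:
            unc_cost += row.complications.uncomplicated * c_unc

    totals = cohort.totals()
    fistula_cost = totals["fistula"] * scenario.value(draw, "cost_fistula_treatment")
    anaemia_cost = totals["anaemia"] * scenario.value(draw, "cost_anaemia_treatment")
    above = (
        cohort.cohort_size * scenario.value(draw, "above_service_cost")
        if scenario.above_service else 0.0
    )
    return CostSummary(
        anc_cost=anc_cost,
        uncomplicated_delivery_cost=unc_cost,
        complicated_delivery_cost=comp_cost,
        fistula_treatment_cost=fistula_cost,
        anaemia_treatment_cost=anaemia_cost,
        above_service_cost=above,
    )
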