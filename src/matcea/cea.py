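"""Cost-effectiveness analysis: deterministic ICER, probabilistic
sensitivity analysis (PSA), acceptability curve, one-way (tornado)
sensitivity analysis and alternative-base-case scenario analysis.

The incremental cost-effectiveness ratio compares an intervention scenario
with a comparator on the same cohort:

    ICER = (cost_intervention - cost_comparator) / (DALYs averted)

An intervention that costs less and is at least as effective is
cost-saving ("CS"); one that costs more and is less effective is
dominated.  Verdicts use the willingness-to-pay convention of one gross
domestic product per capita (Nigeria 2012: US$ 2,730) for "very
cost-effective" and three for "cost-effective".

The PSA uses common random numbers: one parameter draw per iteration
feeds both scenarios, with scenario-scoped entries sampled alongside the
shared ones.  Per-draw ratios are summarised by their median and
2.5/97.5 percentiles; cost-saving draws are ordered below the smallest
ratio and dominated draws above the largest, so the percentile ranks are
well defined even when the ratio is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accounting import CostSummary, HealthSummary, compute_cost, compute_health
from .parameters import (
    ModelConfig,
    ParameterDraw,
    ParameterError,
    ParameterSet,
    ScenarioConfig,
)
from .pathway import CohortTable, run_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "WTP_GDP_PER_CAPITA",
    "CEAResult",
    "PSAResult",
    "TornadoResult",
    "evaluate_scenario",
    "icer",
    "run_point_cea",
    "run_psa",
    "one_way_sa",
    "scenario_analysis",
    "default_wtp_grid",
]

WTP_GDP_PER_CAPITA = 2730.0  # Nigeria, US$ 2012


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid from US$1 to US$5,000."""
    return np.concatenate([[1.0], np.arange(25.0, 5001.0, 25.0)])


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of one intervention against one comparator."""

    delta_cost: float
    delta_effect: float  # DALYs averted (positive favours the intervention)
    icer: float | None
    wtp_threshold: float
    verdict: str
    base_name: str = ""
    intervention_name: str = ""

    def as_dict(self) -> dict:
        return {
            "base": self.base_name,
            "intervention": self.intervention_name,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "wtp_threshold": self.wtp_threshold,
            "verdict": self.verdict,
        }


@dataclass
class PSAResult:
    """Monte-Carlo ensemble of incremental results."""

    n_iter: int
    seed: int
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    median: float
    cri_low: float
    cri_high: float
    ceac: pd.DataFrame  # columns: wtp, probability
    n_cost_saving: int = 0
    n_dominated: int = 0

    @property
    def icers(self) -> np.ndarray:
        """Per-draw ratios on the ordering scale: cost-saving draws are
        -inf, dominated (or undefined with positive cost) draws +inf."""
        return _ordering_values(self.delta_cost, self.delta_effect)

    def draws_frame(self) -> pd.DataFrame:
        ratio = np.where(
            self.delta_effect > 0, self.delta_cost / np.where(
                self.delta_effect > 0, self.delta_effect, np.nan), np.nan)
        return pd.DataFrame({
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": ratio,
            "cost_saving": (self.delta_cost <= 0) & (self.delta_effect >= 0),
        })


@dataclass
class TornadoResult:
    """One-way sensitivity analysis ranked by ICER swing."""

    baseline_icer: float
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    # rows columns: parameter, low_value, high_value, icer_at_low,
    # icer_at_high, swing (sorted by swing, descending)

    def top(self, n: int) -> list[str]:
        return list(self.rows["parameter"].head(n))


def evaluate_scenario(
    draw: ParameterDraw,
    scenario: ScenarioConfig,
    cohort_size: float,
    mode: str = "ledger",
) -> tuple[CohortTable, CostSummary, HealthSummary]:
    """Run the pathway and both accounting layers for one scenario."""
    cohort = run_cohort(draw, scenario, cohort_size)
    cost = compute_cost(cohort, draw, scenario)
    health = compute_health(cohort, draw, mode=mode)
    return cohort, cost, health


def icer(
    base: tuple[CostSummary, HealthSummary],
    intervention: tuple[CostSummary, HealthSummary],
    wtp: float = WTP_GDP_PER_CAPITA,
    base_name: str = "",
    intervention_name: str = "",
) -> CEAResult:
    """Incremental cost-effectiveness of ``intervention`` vs ``base``."""
    base_cost, base_health = base
    int_cost, int_health = intervention
    if base_health.mode != int_health.mode:
        raise ParameterError("scenarios evaluated under different accounting modes")
    dc = int_cost.total_cost - base_cost.total_cost
    de = int_health.gain - base_health.gain  # DALYs averted

    ratio: float | None
    if de > 0 and dc > 0:
        ratio = dc / de
        if ratio <= wtp:
            verdict = "very cost-effective"
        elif ratio <= 3 * wtp:
            verdict = "cost-effective"
        else:
            verdict = "not cost-effective"
    elif de >= 0 and dc <= 0 and (de > 0 or dc < 0):
        ratio = None
        verdict = "cost-saving"
    elif de == 0 and dc == 0:
        ratio = None
        verdict = "equivalent"
    elif de <= 0 and dc >= 0:
        ratio = None
        verdict = "dominated"
    else:  # less effective and cheaper: report the south-west ratio
        ratio = dc / de
        verdict = "not cost-effective"
    return CEAResult(
        delta_cost=dc, delta_effect=de, icer=ratio, wtp_threshold=wtp,
        verdict=verdict, base_name=base_name, intervention_name=intervention_name,
    )


def run_point_cea(
    config: ModelConfig,
    base: str = "soc",
    intervention: str = "kshi",
    wtp: float = WTP_GDP_PER_CAPITA,
    mode: str = "ledger",
) -> CEAResult:
    """Deterministic CEA at parameter point estimates."""
    params = config.merged_params(base, intervention)
    draw = params.point_draw()
    n = params.cohort_size
    _, c_b, h_b = evaluate_scenario(draw, config.scenarios[base], n, mode)
    _, c_i, h_i = evaluate_scenario(draw, config.scenarios[intervention], n, mode)
    return icer((c_b, h_b), (c_i, h_i), wtp, base, intervention)


def _ordering_values(delta_cost: np.ndarray, delta_effect: np.ndarray) -> np.ndarray:
    vals = np.full(delta_cost.shape, np.nan)
    positive = delta_effect > 0
    vals[positive] = delta_cost[positive] / delta_effect[positive]
    saving = (delta_cost <= 0) & (delta_effect >= 0)
    vals[saving] = -np.inf
    undefined = np.isnan(vals)
    vals[undefined] = np.inf  # dominated or undefined with positive cost
    return vals


def _ceac_curve(
    delta_cost: np.ndarray, delta_effect: np.ndarray, wtp_grid: np.ndarray
) -> pd.DataFrame:
    """Probability the intervention is cost-effective at each threshold.

    Decision rule per draw: cost-effective at w iff the draw is cost-saving
    or has positive health gain with ratio <= w.
    """
    ratios = _ordering_values(delta_cost, delta_effect)
    probs = [float(np.mean(ratios <= w)) for w in wtp_grid]
    return pd.DataFrame({"wtp": np.asarray(wtp_grid, dtype=float), "probability": probs})


def run_psa(
    config: ModelConfig,
    base: str = "soc",
    intervention: str = "kshi",
    n_iter: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    mode: str = "ledger",
) -> PSAResult:
    """Paired Monte-Carlo PSA over the parameter distributions."""
    if n_iter < 2:
        raise ParameterError("PSA requires at least 2 iterations")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    params = config.merged_params(base, intervention)
    n = params.cohort_size
    scen_b = config.scenarios[base]
    scen_i = config.scenarios[intervention]
    rng = np.random.default_rng(seed)

    dc = np.empty(n_iter)
    de = np.empty(n_iter)
    for i in range(n_iter):
        draw = params.sample(rng)
        _, c_b, h_b = evaluate_scenario(draw, scen_b, n, mode)
        _, c_i, h_i = evaluate_scenario(draw, scen_i, n, mode)
        dc[i] = c_i.total_cost - c_b.total_cost
        de[i] = h_i.gain - h_b.gain

    order_vals = _ordering_values(dc, de)
    med, lo, hi = np.percentile(order_vals, [50.0, 2.5, 97.5])
    n_cs = int(np.sum(order_vals == -np.inf))
    n_dom = int(np.sum(order_vals == np.inf))
    if n_cs:
        logger.info("PSA: %d/%d draws are cost-saving", n_cs, n_iter)
    if n_dom:
        logger.info("PSA: %d/%d draws are dominated/undefined", n_dom, n_iter)
    return PSAResult(
        n_iter=n_iter, seed=seed, delta_cost=dc, delta_effect=de,
        median=float(med), cri_low=float(lo), cri_high=float(hi),
        ceac=_ceac_curve(dc, de, wtp_grid),
        n_cost_saving=n_cs, n_dominated=n_dom,
    )


def one_way_sa(
    config: ModelConfig,
    base: str = "soc",
    intervention: str = "kshi",
    targets: list[str] | None = None,
    wtp: float = WTP_GDP_PER_CAPITA,
    mode: str = "ledger",
) -> TornadoResult:
    """One-way sensitivity analysis across ``targets`` (default: every
    parameter with non-degenerate bounds), holding all others at their
    point estimates."""
    params = config.merged_params(base, intervention)
    n = params.cohort_size
    scen_b = config.scenarios[base]
    scen_i = config.scenarios[intervention]
    point = params.point_draw()

    def point_icer(draw: ParameterDraw) -> float:
        _, c_b, h_b = evaluate_scenario(draw, scen_b, n, mode)
        _, c_i, h_i = evaluate_scenario(draw, scen_i, n, mode)
        res = icer((c_b, h_b), (c_i, h_i), wtp)
        if res.icer is not None:
            return res.icer
        return -np.inf if res.verdict == "cost-saving" else np.inf

    baseline = point_icer(point)

    if targets is None:
        targets = [k for k in sorted(params.entries)
                   if params.entries[k].one_way_bounds()[0]
                   != params.entries[k].one_way_bounds()[1]]
    rows = []
    for name in targets:
        if name not in params.entries:
            raise ParameterError(f"unknown one-way target {name!r}")
        lo, hi = params.entries[name].one_way_bounds()
        icers = []
        for bound in (lo, hi):
            draw = ParameterDraw(point)
            draw[name] = bound
            icers.append(point_icer(draw))
        if lo == hi:
            swing = 0.0
        elif np.isfinite(icers[0]) and np.isfinite(icers[1]):
            swing = abs(icers[1] - icers[0])
        else:
            swing = np.inf
        rows.append({
            "parameter": name, "low_value": lo, "high_value": hi,
            "icer_at_low": icers[0], "icer_at_high": icers[1], "swing": swing,
        })
    frame = (pd.DataFrame(rows)
             .sort_values("swing", ascending=False, kind="mergesort")
             .reset_index(drop=True))
    return TornadoResult(baseline_icer=baseline, rows=frame)


def scenario_analysis(
    config: ModelConfig,
    alt_bases: list[str] | None = None,
    intervention: str = "kshi",
    wtp: float = WTP_GDP_PER_CAPITA,
    mode: str = "ledger",
) -> list[CEAResult]:
    """ICER of the intervention against each alternative base case."""
    if alt_bases is None:
        alt_bases = [s for s in config.scenarios
                     if s not in (intervention,) and not config.scenarios[s].comparator]
    return [run_point_cea(config, base=b, intervention=intervention, wtp=wtp, mode=mode)
            for b in alt_bases]
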