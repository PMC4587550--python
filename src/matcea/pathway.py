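"""Expectation-based cohort engine for the maternal care pathway.

A cohort of pregnant women is propagated, in expectation, through
antenatal care (ANC) attendance, delivery location (health facility or
home), access to essential obstetric care (EOC), incidence of one of four
delivery complications (post-partum haemorrhage, sepsis, hypertensive
disorders, obstructed labour) or an uncomplicated delivery, and finally
death and sequela outcomes.  All arithmetic is on expected (real-valued)
counts; rounding happens only when printing.

Structure of the tree
---------------------
* ANC attendance splits the cohort into two strata.
* Each stratum splits by delivery location.  ANC attendees use the
  facility/home probabilities renormalized to sum to one (the published
  pair 0.96/0.05 sums to 1.01) unless the scenario pins an explicit
  share; the no-ANC facility share is a calibrated structural default.
* Facility deliveries access EOC with the scenario's probability
  (1 under the insurance program); home deliveries access EOC, i.e. an
  emergency referral, with the shared home-EOC probability.
* Complications are mutually exclusive and exhaustive with
  "uncomplicated".  Haemorrhage and obstructed labour incidence is
  independent of care; sepsis incidence is multiplied by a relative risk
  for hospital (facility) deliveries, with the base rate calibrated via
  the scenario's ``sepsis_calibration`` ratio; hypertensive-disorder
  incidence is multiplied by a prophylaxis relative risk for the covered
  fraction of ANC attendees.
* Deaths: haemorrhage deaths are reduced by a relative risk under EOC;
  obstructed-labour death occurs only without EOC; sepsis and
  hypertensive-disorder case fatality are not further modified by EOC.
* Sequelae arise among survivors only: fistula after obstructed labour
  without EOC, anaemia after haemorrhage (halved under EOC), secondary
  infertility after sepsis.  Surviving hypertensive-disorder cases are
  tracked for the extended-morbidity weight used by the accounting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .parameters import (
    ParameterDraw,
    ParameterError,
    ParameterSet,
    ScenarioConfig,
)

__all__ = [
    "Stratum",
    "ComplicationCounts",
    "OutcomeCounts",
    "CohortRow",
    "CohortTable",
    "stratify",
    "complication_incidence",
    "outcome_resolution",
    "run_cohort",
]

COMPLICATIONS = ("pph", "sepsis", "htd", "ol")

_CONSERVATION_TOL = 1e-9


def _check_prob(value: float, what: str) -> float:
    if not -1e-12 <= value <= 1 + 1e-12:
        raise ParameterError(f"{what} = {value} outside [0, 1]")
    return min(max(value, 0.0), 1.0)


@dataclass(frozen=True)
class Stratum:
    """Expected number of women in one (ANC, location, EOC) cell."""

    anc: bool
    facility: bool
    eoc: bool
    n_women: float


@dataclass(frozen=True)
class ComplicationCounts:
    """Expected complication counts within a stratum (mutually exclusive)."""

    pph: float
    sepsis: float
    htd: float
    ol: float
    uncomplicated: float

    @property
    def complicated(self) -> float:
        return self.pph + self.sepsis + self.htd + self.ol

    @property
    def total(self) -> float:
        return self.complicated + self.uncomplicated


@dataclass(frozen=True)
class OutcomeCounts:
    """Expected deaths and sequelae within a stratum."""

    deaths: float
    fistula: float
    anaemia: float
    infertility: float
    deaths_by_complication: dict[str, float] = field(default_factory=dict)
    htd_survivors: float = 0.0


@dataclass(frozen=True)
class CohortRow:
    stratum: Stratum
    complications: ComplicationCounts
    outcomes: OutcomeCounts


@dataclass
class CohortTable:
    """Full cohort distribution, one row per (ANC, location, EOC) cell."""

    scenario: str
    cohort_size: float
    rows: list[CohortRow]

    def __post_init__(self) -> None:
        total = sum(r.stratum.n_women for r in self.rows)
        if abs(total - self.cohort_size) > _CONSERVATION_TOL * max(1.0, self.cohort_size):
            raise ParameterError(
                f"cohort not conserved: strata sum {total} vs size {self.cohort_size}"
            )

    # -- aggregation ---------------------------------------------------

    def total(self, attr: str) -> float:
        """Cohort-wide total of a complication or outcome field."""
        out = 0.0
        for r in self.rows:
            if hasattr(r.complications, attr):
                out += getattr(r.complications, attr)
            else:
                out += getattr(r.outcomes, attr)
        return out

    def totals(self) -> dict[str, float]:
        keys = ("pph", "sepsis", "htd", "ol", "uncomplicated", "complicated",
                "deaths", "fistula", "anaemia", "infertility", "htd_survivors")
        return {k: self.total(k) for k in keys}

    def anc_attendees(self) -> float:
        return sum(r.stratum.n_women for r in self.rows if r.stratum.anc)

    def to_frame(self) -> pd.DataFrame:
        """One row per (ANC, location, EOC) cell with all expected counts."""
        recs = []
        for r in self.rows:
            recs.append({
                "scenario": self.scenario,
                "anc": r.stratum.anc,
                "facility": r.stratum.facility,
                "eoc": r.stratum.eoc,
                "n_women": r.stratum.n_women,
                "pph": r.complications.pph,
                "sepsis": r.complications.sepsis,
                "htd": r.complications.htd,
                "ol": r.complications.ol,
                "uncomplicated": r.complications.uncomplicated,
                "deaths": r.outcomes.deaths,
                "fistula": r.outcomes.fistula,
                "anaemia": r.outcomes.anaemia,
                "infertility": r.outcomes.infertility,
                "htd_survivors": r.outcomes.htd_survivors,
            })
        return pd.DataFrame(recs)

    def summary_frame(self) -> pd.DataFrame:
        """Published-table layout: ANC stratum x EOC access, location merged."""
        df = self.to_frame()
        grouped = (
            df.groupby(["anc", "eoc"], as_index=False)
            .sum(numeric_only=True)
            .sort_values(["anc", "eoc"], ascending=[True, True])
        )
        grouped.insert(0, "scenario", self.scenario)
        return grouped.reset_index(drop=True)


def stratify(
    cohort_size: float, draw: ParameterDraw, scenario: ScenarioConfig
) -> list[Stratum]:
    """Split the cohort by ANC attendance, delivery location and EOC access."""
    if cohort_size < 0:
        raise ParameterError("cohort size must be non-negative")
    p_anc = _check_prob(scenario.value(draw, "anc_access"), "ANC access")
    if scenario.anc_facility_share is not None:
        f_anc = scenario.anc_facility_share
    else:
        fac = scenario.value(draw, "facility_if_anc")
        home = scenario.value(draw, "home_if_anc")
        f_anc = fac / (fac + home)  # published pair sums to 1.01
    f_anc = _check_prob(f_anc, "facility share, ANC stratum")
    f_no = _check_prob(scenario.noanc_facility_share, "facility share, no-ANC stratum")
    p_eoc_fac = _check_prob(scenario.value(draw, "eoc_if_facility"), "EOC | facility")
    p_eoc_home = _check_prob(scenario.value(draw, "eoc_if_home"), "EOC | home")

    strata = []
    for anc, (n, f) in ((True, (cohort_size * p_anc, f_anc)),
                        (False, (cohort_size * (1.0 - p_anc), f_no))):
        for facility, loc_share in ((True, f), (False, 1.0 - f)):
            p_eoc = p_eoc_fac if facility else p_eoc_home
            for eoc, eoc_share in ((True, p_eoc), (False, 1.0 - p_eoc)):
                strata.append(
                    Stratum(anc=anc, facility=facility, eoc=eoc,
                            n_women=n * loc_share * eoc_share)
                )
    return strata


def complication_incidence(
    stratum: Stratum, draw: ParameterDraw, scenario: ScenarioConfig
) -> ComplicationCounts:
    """Expected complication counts for one stratum.

    Haemorrhage and obstructed labour are independent of care.  Sepsis is
    reduced by the hospital relative risk for facility deliveries; the base
    rate is the sepsis parameter times the scenario's calibration ratio.
    Hypertensive disorders are reduced by the prophylaxis relative risk for
    the covered fraction of ANC attendees.
    """
    p_pph = _check_prob(scenario.value(draw, "p_pph"), "haemorrhage incidence")
    p_ol = _check_prob(scenario.value(draw, "p_ol"), "obstructed-labour incidence")
    p_htd = scenario.value(draw, "p_htd")
    if stratum.anc:
        rr = scenario.value(draw, "rr_htd_anc")
        cov = scenario.htd_prophylaxis_coverage
        p_htd = p_htd * (1.0 - (1.0 - rr) * cov)
    p_htd = _check_prob(p_htd, "hypertensive-disorder incidence")
    p_sep = scenario.value(draw, "p_sepsis") * scenario.sepsis_calibration
    if stratum.facility:
        p_sep *= scenario.value(draw, "rr_sepsis_hospital")
    p_sep = _check_prob(p_sep, "sepsis incidence")

    total = p_pph + p_sep + p_htd + p_ol
    if total > 1.0:
        raise ParameterError(f"complication probabilities sum to {total} > 1")
    n = stratum.n_women
    return ComplicationCounts(
        pph=n * p_pph, sepsis=n * p_sep, htd=n * p_htd, ol=n * p_ol,
        uncomplicated=n * (1.0 - total),
    )


def outcome_resolution(
    comp: ComplicationCounts, stratum: Stratum, draw: ParameterDraw,
    scenario: ScenarioConfig | None = None,
) -> OutcomeCounts:
    """Deaths and sequelae for one stratum's complication counts."""
    resolve = (lambda name: scenario.value(draw, name)) if scenario else (
        lambda name: draw.resolve(name))
    d_pph = resolve("p_death_pph")
    if stratum.eoc:
        d_pph *= resolve("rr_pph_death_eoc")
    d_sep = resolve("p_death_sepsis")
    d_htd = resolve("p_death_htd")
    d_ol = 0.0 if stratum.eoc else resolve("p_death_ol")

    deaths_by = {
        "pph": comp.pph * d_pph,
        "sepsis": comp.sepsis * d_sep,
        "htd": comp.htd * d_htd,
        "ol": comp.ol * d_ol,
    }
    p_ana = resolve("p_anaemia_pph")
    if stratum.eoc:
        p_ana *= resolve("rr_anaemia_eoc")
    anaemia = (comp.pph - deaths_by["pph"]) * p_ana
    fistula = 0.0 if stratum.eoc else (comp.ol - deaths_by["ol"]) * resolve("p_fistula_ol")
    infertility = (comp.sepsis - deaths_by["sepsis"]) * resolve("p_infertility_sepsis")

    return OutcomeCounts(
        deaths=sum(deaths_by.values()),
        fistula=fistula,
        anaemia=anaemia,
        infertility=infertility,
        deaths_by_complication=deaths_by,
        htd_survivors=comp.htd - deaths_by["htd"],
    )


def run_cohort(
    params_or_draw: ParameterSet | ParameterDraw,
    scenario: ScenarioConfig,
    cohort_size: float | None = None,
) -> CohortTable:
    """Propagate the cohort through the full pathway.

    Accepts either a :class:`ParameterSet` (evaluated at its point
    estimates) or a concrete :class:`ParameterDraw`.
    """
    if isinstance(params_or_draw, ParameterSet):
        draw = params_or_draw.merged(scenario.override_entries()).point_draw()
        if cohort_size is None:
            cohort_size = params_or_draw.cohort_size
    else:
        draw = params_or_draw
        if cohort_size is None:
            raise ParameterError("cohort_size is required when passing a raw draw")

    rows = []
    for stratum in stratify(cohort_size, draw, scenario):
        comp = complication_incidence(stratum, draw, scenario)
        out = outcome_resolution(comp, stratum, draw, scenario)
        rows.append(CohortRow(stratum=stratum, complications=comp, outcomes=out))
    return CohortTable(scenario=scenario.name, cohort_size=cohort_size, rows=rows)
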