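"""Individual-level Monte-Carlo simulator over the same care pathway.

Each simulated pregnancy is one record resembling an insurance-claims row:
ANC attendance (and number of visits), delivery location, EOC access,
complication, death, sequela, and the provider cost and DALY loss the
record incurs under the same rules as the expectation engine.  Because
every decision is a Bernoulli/categorical draw with exactly the pathway
probabilities, cell frequencies converge to the cohort engine's expected
counts, which makes the simulator the validation oracle for the
expectation-based model (and vice versa).

Randomness is consumed in a fixed documented order per batch of records:
ANC attendance, visit count, delivery location, EOC access, hypertensive
prophylaxis assignment, complication category, death, sequela.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accounting import REFERENCE_DISCOUNT_RATE  # noqa: F401  (shared convention)
from .parameters import ParameterDraw, ParameterError, ScenarioConfig
from .pathway import CohortRow, CohortTable, ComplicationCounts, OutcomeCounts, Stratum

__all__ = ["RECORD_COLUMNS", "simulate_individuals", "aggregate"]

RECORD_COLUMNS = [
    "id", "scenario", "anc", "n_anc_visits", "delivery_location", "eoc",
    "complication", "death", "sequela", "cost_incurred", "daly_incurred",
]


def simulate_individuals(
    n: int, draw: ParameterDraw, scenario: ScenarioConfig, seed: int
) -> pd.DataFrame:
    """Simulate ``n`` pregnancies; reproducible for a fixed seed."""
    if n < 1:
        raise ParameterError("need at least one pregnancy to simulate")
    rng = np.random.default_rng(seed)
    val = lambda name: scenario.value(draw, name)  # noqa: E731

    anc = rng.random(n) < val("anc_access")
    # ANC attendees make 3-5 visits per pregnancy (observed range).
    n_visits = np.where(anc, rng.integers(3, 6, size=n), 0)

    if scenario.anc_facility_share is not None:
        f_anc = scenario.anc_facility_share
    else:
        f_anc = val("facility_if_anc") / (val("facility_if_anc") + val("home_if_anc"))
    f_share = np.where(anc, f_anc, scenario.noanc_facility_share)
    facility = rng.random(n) < f_share
    p_eoc = np.where(facility, val("eoc_if_facility"), val("eoc_if_home"))
    eoc = rng.random(n) < p_eoc
    prophylaxis = anc & (rng.random(n) < scenario.htd_prophylaxis_coverage)

    p_pph = np.full(n, val("p_pph"))
    p_sep = val("p_sepsis") * scenario.sepsis_calibration * np.where(
        facility, val("rr_sepsis_hospital"), 1.0)
    p_htd = val("p_htd") * np.where(prophylaxis, val("rr_htd_anc"), 1.0)
    p_ol = np.full(n, val("p_ol"))

    # complication category by inverse-CDF on one uniform per record
    u = rng.random(n)
    edges = np.cumsum(np.column_stack([p_pph, p_sep, p_htd, p_ol]), axis=1)
    if np.any(edges[:, -1] > 1.0):
        raise ParameterError("complication probabilities sum above 1")
    comp_idx = (u[:, None] < edges).argmax(axis=1)
    comp_idx = np.where(u < edges[:, -1], comp_idx, 4)  # 4 = uncomplicated
    complication = np.array(["pph", "sepsis", "htd", "ol", "none"])[comp_idx]

    p_death = np.zeros(n)
    p_death[complication == "pph"] = val("p_death_pph") * np.where(
        eoc[complication == "pph"], val("rr_pph_death_eoc"), 1.0)
    p_death[complication == "sepsis"] = val("p_death_sepsis")
    p_death[complication == "htd"] = val("p_death_htd")
    p_death[complication == "ol"] = np.where(
        eoc[complication == "ol"], 0.0, val("p_death_ol"))
    death = rng.random(n) < p_death

    p_seq = np.zeros(n)
    alive = ~death
    is_pph = complication == "pph"
    is_sep = complication == "sepsis"
    is_ol = complication == "ol"
    p_seq[is_pph] = val("p_anaemia_pph") * np.where(
        eoc[is_pph], val("rr_anaemia_eoc"), 1.0)
    p_seq[is_sep] = val("p_infertility_sepsis")
    p_seq[is_ol & ~eoc] = val("p_fistula_ol")
    has_seq = alive & (rng.random(n) < p_seq)
    sequela = np.full(n, "none", dtype=object)
    sequela[has_seq & is_pph] = "anaemia"
    sequela[has_seq & is_sep] = "infertility"
    sequela[has_seq & is_ol] = "fistula"

    complicated = complication != "none"
    cost = np.where(anc, val("cost_anc"), 0.0)
    cost += np.where(
        complicated & eoc, val("cost_delivery_complicated"),
        np.where(facility, val("cost_delivery_uncomplicated"), 0.0))
    cost += np.where(sequela == "fistula", val("cost_fistula_treatment"), 0.0)
    cost += np.where(sequela == "anaemia", val("cost_anaemia_treatment"), 0.0)
    if scenario.above_service:
        cost += val("above_service_cost")

    daly = np.where(death, val("daly_death"), 0.0)
    daly += np.where(sequela == "anaemia", val("daly_anaemia"), 0.0)
    daly += np.where(sequela == "infertility", val("daly_infertility"), 0.0)
    daly += np.where(sequela == "fistula", val("daly_fistula"), 0.0)
    daly += np.where((complication == "htd") & alive, val("daly_extended_htd"), 0.0)

    return pd.DataFrame({
        "id": np.arange(n),
        "scenario": scenario.name,
        "anc": anc,
        "n_anc_visits": n_visits,
        "delivery_location": np.where(facility, "facility", "home"),
        "eoc": eoc,
        "complication": complication,
        "death": death,
        "sequela": sequela,
        "cost_incurred": cost,
        "daly_incurred": daly,
    }, columns=RECORD_COLUMNS)


def aggregate(records: pd.DataFrame) -> CohortTable:
    """Collapse claims-like records into the cohort-table shape."""
    if len(records) == 0:
        raise ParameterError("cannot aggregate an empty record set")
    scenario = records["scenario"].iloc[0]
    rows = []
    facility_flag = records["delivery_location"] == "facility"
    for anc in (True, False):
        for facility in (True, False):
            for eoc in (True, False):
                sel = records[(records["anc"] == anc)
                              & (facility_flag == facility)
                              & (records["eoc"] == eoc)]
                if len(sel) == 0:
                    continue
                comp_n = sel["complication"].value_counts()
                comp = ComplicationCounts(
                    pph=float(comp_n.get("pph", 0)),
                    sepsis=float(comp_n.get("sepsis", 0)),
                    htd=float(comp_n.get("htd", 0)),
                    ol=float(comp_n.get("ol", 0)),
                    uncomplicated=float(comp_n.get("none", 0)),
                )
                deaths_by = {
                    c: float(((sel["complication"] == c) & sel["death"]).sum())
                    for c in ("pph", "sepsis", "htd", "ol")
                }
                seq_n = sel.loc[~sel["death"], "sequela"].value_counts()
                out = OutcomeCounts(
                    deaths=float(sel["death"].sum()),
                    fistula=float(seq_n.get("fistula", 0)),
                    anaemia=float(seq_n.get("anaemia", 0)),
                    infertility=float(seq_n.get("infertility", 0)),
                    deaths_by_complication=deaths_by,
                    htd_survivors=float(
                        ((sel["complication"] == "htd") & ~sel["death"]).sum()),
                )
                rows.append(CohortRow(
                    stratum=Stratum(anc=anc, facility=facility, eoc=eoc,
                                    n_women=float(len(sel))),
                    complications=comp, outcomes=out,
                ))
    return CohortTable(scenario=scenario, cohort_size=float(len(records)), rows=rows)
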