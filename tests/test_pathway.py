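"""Cohort engine: stratification, incidence, outcomes and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matcea import (
    ComplicationCounts,
    ParameterError,
    Stratum,
    complication_incidence,
    outcome_resolution,
    run_cohort,
    sample_draw,
    stratify,
)


def anc_count(strata, anc):
    return sum(s.n_women for s in strata if s.anc == anc)


class TestStratify:
    def test_soc_anc_split(self, config, point_draw):
        strata = stratify(10_000, point_draw, config.scenarios["soc"])
        assert anc_count(strata, False) == pytest.approx(3_500)
        assert anc_count(strata, True) == pytest.approx(6_500)

    def test_kshi_anc_split(self, config, point_draw):
        strata = stratify(10_000, point_draw, config.scenarios["kshi"])
        assert anc_count(strata, False) == pytest.approx(1_500)
        assert anc_count(strata, True) == pytest.approx(8_500)

    def test_full_anc_access_single_stratum(self, config, point_draw):
        draw = dict(point_draw)
        draw["anc_access@soc"] = 1.0
        from matcea import ParameterDraw

        strata = stratify(10_000, ParameterDraw(draw), config.scenarios["soc"])
        assert anc_count(strata, True) == pytest.approx(10_000)
        assert anc_count(strata, False) == pytest.approx(0.0)

    def test_conservation(self, config, point_draw):
        for name in ("soc", "kshi"):
            strata = stratify(10_000, point_draw, config.scenarios[name])
            assert sum(s.n_women for s in strata) == pytest.approx(10_000, abs=1e-9)

    def test_anc_delivery_split_renormalized(self, config, point_draw):
        # facility 0.96 / home 0.05 sum to 1.01 and are renormalized
        strata = stratify(10_000, point_draw, config.scenarios["soc"])
        fac = sum(s.n_women for s in strata if s.anc and s.facility)
        assert fac / 6_500 == pytest.approx(0.96 / 1.01)


class TestComplicationIncidence:
    def test_pph_and_ol_independent_of_care(self, config, point_draw):
        # haemorrhage and obstructed labour rates identical across strata
        for name in ("soc", "kshi"):
            scen = config.scenarios[name]
            for stratum in stratify(10_000, point_draw, scen):
                comp = complication_incidence(stratum, point_draw, scen)
                if stratum.n_women > 0:
                    assert comp.pph / stratum.n_women == pytest.approx(0.051)
                    assert comp.ol / stratum.n_women == pytest.approx(0.06)

    def test_kshi_anc_htd_prophylaxis(self, config, point_draw):
        # full prophylaxis coverage: 8,500 * 0.085 * 0.41 = 296 cases
        scen = config.scenarios["kshi"]
        cohort = run_cohort(point_draw, scen, 10_000)
        htd_anc = sum(r.complications.htd for r in cohort.rows if r.stratum.anc)
        assert round(htd_anc) == pytest.approx(296, abs=1)

    def test_sepsis_reduced_in_facility(self, config, point_draw):
        scen = config.scenarios["soc"]
        fac = Stratum(anc=True, facility=True, eoc=True, n_women=1000.0)
        home = Stratum(anc=True, facility=False, eoc=False, n_women=1000.0)
        c_fac = complication_incidence(fac, point_draw, scen)
        c_home = complication_incidence(home, point_draw, scen)
        assert c_fac.sepsis / c_home.sepsis == pytest.approx(0.54)

    def test_zero_stratum_all_zero(self, config, point_draw):
        stratum = Stratum(anc=False, facility=False, eoc=False, n_women=0.0)
        comp = complication_incidence(stratum, point_draw, config.scenarios["soc"])
        assert comp.total == 0.0


class TestOutcomeResolution:
    def test_no_eoc_substratum_death_toll(self, config, point_draw):
        # midpoint death probabilities (0.1505, 0.3635, 0.083, 0.007)
        # applied to the published no-ANC/no-EOC complication mix
        comp = ComplicationCounts(pph=149, sepsis=55, htd=248, ol=175, uncomplicated=0)
        stratum = Stratum(anc=False, facility=False, eoc=False, n_women=627)
        out = outcome_resolution(comp, stratum, point_draw, config.scenarios["soc"])
        assert out.deaths == pytest.approx(64.23, abs=0.05)

    def test_eoc_substratum_death_toll(self, config, point_draw):
        # EOC: haemorrhage deaths x 0.34, obstructed-labour deaths -> 0
        comp = ComplicationCounts(pph=30, sepsis=10, htd=50, ol=35, uncomplicated=0)
        stratum = Stratum(anc=False, facility=True, eoc=True, n_women=125)
        out = outcome_resolution(comp, stratum, point_draw, config.scenarios["soc"])
        assert out.deaths == pytest.approx(9.32, abs=0.01)
        assert out.deaths_by_complication["ol"] == 0.0
        assert out.fistula == 0.0  # fistula only without EOC

    def test_all_zero_complications(self, config, point_draw):
        comp = ComplicationCounts(pph=0, sepsis=0, htd=0, ol=0, uncomplicated=100)
        stratum = Stratum(anc=True, facility=True, eoc=True, n_women=100)
        out = outcome_resolution(comp, stratum, point_draw, config.scenarios["soc"])
        assert out.deaths == out.fistula == out.anaemia == out.infertility == 0.0

    def test_sequelae_bounded_by_survivors(self, config, point_draw):
        comp = ComplicationCounts(pph=100, sepsis=100, htd=100, ol=100, uncomplicated=0)
        stratum = Stratum(anc=False, facility=False, eoc=False, n_women=400)
        out = outcome_resolution(comp, stratum, point_draw, config.scenarios["soc"])
        assert out.anaemia <= 100 - out.deaths_by_complication["pph"]
        assert out.infertility <= 100 - out.deaths_by_complication["sepsis"]
        assert out.fistula <= 100 - out.deaths_by_complication["ol"]


class TestRunCohort:
    def test_complication_totals(self, config, point_draw):
        for name in ("soc", "kshi"):
            totals = run_cohort(point_draw, config.scenarios[name], 10_000).totals()
            assert round(totals["pph"]) == pytest.approx(510, abs=1)
            assert round(totals["ol"]) == pytest.approx(600, abs=1)

    def test_death_totals(self, config, point_draw):
        soc = run_cohort(point_draw, config.scenarios["soc"], 10_000).totals()
        kshi = run_cohort(point_draw, config.scenarios["kshi"], 10_000).totals()
        assert round(soc["deaths"]) == pytest.approx(157, abs=1)
        assert round(kshi["deaths"]) == pytest.approx(110, abs=1)
        assert round(soc["deaths"] - kshi["deaths"]) == pytest.approx(47, abs=1)

    def test_accepts_parameter_set(self, config):
        cohort = run_cohort(config.params, config.scenarios["soc"])
        assert cohort.cohort_size == 10_000

    def test_raw_draw_requires_cohort_size(self, config, point_draw):
        with pytest.raises(ParameterError):
            run_cohort(point_draw, config.scenarios["soc"])

    def test_summary_frame_shape(self, config, point_draw):
        frame = run_cohort(point_draw, config.scenarios["soc"], 10_000).summary_frame()
        assert len(frame) == 4  # ANC x EOC
        assert frame["n_women"].sum() == pytest.approx(10_000)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_conservation_under_random_draws(seed):
    """Expected counts sum to the cohort size at every stage for any draw."""
    from matcea import default_config

    config = default_config()
    params = config.merged_params("soc", "kshi")
    draw = sample_draw(params, seed)
    for name in ("soc", "kshi"):
        cohort = run_cohort(draw, config.scenarios[name], 10_000)
        totals = cohort.totals()
        assert totals["complicated"] + totals["uncomplicated"] == pytest.approx(
            10_000, abs=1e-6)
        assert totals["deaths"] <= totals["complicated"]


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(0.01, 25.0), seed=st.integers(0, 10_000))
def test_scale_equivariance(scale, seed):
    """Running k*N women yields k-times every expected count."""
    from matcea import default_config

    config = default_config()
    draw = sample_draw(config.merged_params("soc", "kshi"), seed)
    base = run_cohort(draw, config.scenarios["kshi"], 10_000).totals()
    scaled = run_cohort(draw, config.scenarios["kshi"], 10_000 * scale).totals()
    for key, value in base.items():
        assert scaled[key] == pytest.approx(value * scale, rel=1e-9)


def test_more_eoc_never_increases_deaths(config, point_draw):
    from matcea import ParameterDraw

    deaths = []
    for p_eoc in np.linspace(0.5, 1.0, 6):
        draw = ParameterDraw(point_draw)
        draw["eoc_if_facility@soc"] = p_eoc
        deaths.append(run_cohort(draw, config.scenarios["soc"], 10_000).totals()["deaths"])
    assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(deaths, deaths[1:]))


def test_more_anc_never_increases_htd_in_kshi(config, point_draw):
    from matcea import ParameterDraw

    htd = []
    for p_anc in np.linspace(0.5, 1.0, 6):
        draw = ParameterDraw(point_draw)
        draw["anc_access@kshi"] = p_anc
        htd.append(run_cohort(draw, config.scenarios["kshi"], 10_000).totals()["htd"])
    assert all(h2 <= h1 + 1e-9 for h1, h2 in zip(htd, htd[1:]))
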