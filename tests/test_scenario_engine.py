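"""Scenario engine: common-random-number guarantees, population
scaling, person-years projection, and cross-scenario invariants."""

from dataclasses import replace

import numpy as np
import pytest

from crcsim.params import (
    LifeTable,
    PopulationPyramid,
    ProgrammeDesign,
    ScreeningTest,
)
from crcsim.scenario_engine import (
    RawOutcomes,
    ScalingFactors,
    Scenario,
    person_years_projection,
    run_comparison,
    scale_to_population,
)


def scenario_fit(params, **kw):
    base = dict(
        test_name="FIT",
        start_age=55,
        stop_age=75,
        interval=2,
        participation=0.713,
        followup_adherence=0.85,
        start_year=2018,
    )
    base.update(kw)
    return Scenario(kw.get("label", "FIT"), ProgrammeDesign(**{k: v for k, v in base.items() if k != "label"}))


@pytest.fixture(scope="module")
def small_run(western):
    scenarios = [
        Scenario.no_screening(),
        Scenario.current_programme(western, "FIT"),
        Scenario(
            "Colonoscopy",
            ProgrammeDesign(
                test_name="colonoscopy", start_age=55, stop_age=75, interval=5,
                participation=0.713, followup_adherence=0.85, start_year=2018,
            ),
        ),
    ]
    raws, factors = run_comparison(western, scenarios, n_sim=25_000, master_seed=17)
    return western, scenarios, raws, factors


class TestCommonRandomNumbers:
    def test_two_no_screening_scenarios_identical(self, western):
        scenarios = [Scenario.no_screening("A"), Scenario.no_screening("B")]
        raws, factors = run_comparison(western, scenarios, n_sim=12_000, master_seed=3)
        a = scale_to_population(raws["A"], factors)
        b = scale_to_population(raws["B"], factors)
        assert a.equals(b)

    def test_zero_participation_equals_no_screening_bitwise(self, western):
        scenarios = [
            Scenario.no_screening(),
            scenario_fit(western, participation=0.0, label="dead FIT"),
        ]
        # strip the pre-2018 programme history so no screening happens at all
        params = replace(western, programme_history=())
        raws, factors = run_comparison(params, scenarios, n_sim=12_000, master_seed=3)
        a = scale_to_population(raws["No screening"], factors)
        b = scale_to_population(raws["dead FIT"], factors)
        assert a.equals(b)

    def test_zero_sensitivity_perfect_specificity_leaves_outcomes_unchanged(self, western):
        blind = ScreeningTest(name="FIT", sensitivity_by_state={}, specificity=1.0)
        params = replace(
            western,
            programme_history=(),
            tests={**western.tests, "FIT": blind},
        )
        scenarios = [Scenario.no_screening(), scenario_fit(params, label="blind FIT")]
        raws, factors = run_comparison(params, scenarios, n_sim=12_000, master_seed=3)
        a = scale_to_population(raws["No screening"], factors)
        b = scale_to_population(raws["blind FIT"], factors)
        # tests happen but change nothing
        assert b.total("tests_FIT") > 0
        assert np.array_equal(a.counts["crc_cases"], b.counts["crc_cases"])
        assert np.array_equal(a.counts["crc_deaths"], b.counts["crc_deaths"])
        assert b.total("positives") == 0

    def test_reproducibility_same_seed(self, western):
        scenarios = [Scenario.no_screening(), Scenario.current_programme(western, "FIT")]
        r1, f1 = run_comparison(western, scenarios, n_sim=8_000, master_seed=5)
        r2, f2 = run_comparison(western, scenarios, n_sim=8_000, master_seed=5)
        for lab in ("No screening", "FIT"):
            a = scale_to_population(r1[lab], f1)
            b = scale_to_population(r2[lab], f2)
            assert a.equals(b)


class TestAccountingChain:
    def test_stool_test_chain(self, small_run):
        _, _, raws, factors = small_run
        o = scale_to_population(raws["FIT"], factors)
        tests = o.total("tests_FIT")
        positives = o.total("positives")
        followups = o.total("followup_colonoscopies")
        cancers = o.total("cancers_detected")
        assert tests >= positives >= followups >= cancers
        assert o.total("false_positives") <= positives

    def test_direct_visualization_reports_no_followups_or_false_positives(self, small_run):
        _, _, raws, factors = small_run
        o = scale_to_population(raws["Colonoscopy"], factors)
        assert o.total("tests_colonoscopy") > 0
        assert o.total("followup_colonoscopies") == 0
        assert o.total("false_positives") == 0

    def test_screening_reduces_cases_and_deaths(self, small_run):
        _, _, raws, factors = small_run
        none = scale_to_population(raws["No screening"], factors)
        fit = scale_to_population(raws["FIT"], factors)
        assert fit.total("crc_cases", 40, 100) < none.total("crc_cases", 40, 100)
        assert fit.total("crc_deaths", 40, 100) < none.total("crc_deaths", 40, 100)

    def test_case_count_includes_screen_detected(self, small_run):
        # screen-detected cancers appear in the case count of their year
        _, _, raws, factors = small_run
        o = scale_to_population(raws["FIT"], factors)
        assert o.total("crc_cases") >= o.total("cancers_detected")


class TestScaling:
    def _raw(self, rng):
        counts = {"crc_cases": rng.poisson(3.0, size=(4, 5, 21)).astype(float)}
        return RawOutcomes(
            years=np.arange(2018, 2023),
            band_edges=np.arange(0, 110, 5),
            birth_years=np.arange(1950, 1954),
            n_per_cohort=100,
            counts=counts,
        )

    def test_unit_factors_identity(self, rng):
        raw = self._raw(rng)
        f = ScalingFactors(raw.birth_years, np.ones(4))
        out = scale_to_population(raw, f)
        assert np.array_equal(out.counts["crc_cases"], raw.counts["crc_cases"].sum(axis=0))

    def test_double_factors_double_counts(self, rng):
        raw = self._raw(rng)
        f1 = ScalingFactors(raw.birth_years, np.ones(4))
        f2 = ScalingFactors(raw.birth_years, np.full(4, 2.0))
        a = scale_to_population(raw, f1)
        b = scale_to_population(raw, f2)
        assert np.array_equal(b.counts["crc_cases"], 2.0 * a.counts["crc_cases"])

    def test_mixed_factors_match_brute_force(self, rng):
        raw = self._raw(rng)
        factors = rng.uniform(0.5, 3.0, size=4)
        out = scale_to_population(raw, ScalingFactors(raw.birth_years, factors))
        brute = np.zeros((5, 21))
        for c in range(4):
            brute += factors[c] * raw.counts["crc_cases"][c]
        assert np.allclose(out.counts["crc_cases"], brute)

    def test_missing_cohort_factor_errors(self, rng):
        raw = self._raw(rng)
        f = ScalingFactors(np.arange(1950, 1953), np.ones(3))
        with pytest.raises(ValueError):
            scale_to_population(raw, f)

    def test_aggregation_conservation(self, small_run):
        _, _, raws, factors = small_run
        o = scale_to_population(raws["FIT"], factors)
        total_direct = o.counts["crc_cases"].sum()
        per_year = o.per_year("crc_cases", 0, 104).sum()
        assert total_direct == pytest.approx(per_year, rel=1e-12)


class TestPersonYears:
    def test_single_immortal_person_33_years(self):
        qx = np.zeros(101)
        qx[-1] = 1.0
        lt = LifeTable(age=np.arange(101), qx=qx)
        count = np.zeros(101)
        count[50] = 1.0
        pyr = PopulationPyramid(age=np.arange(101), count=count)
        py = person_years_projection(pyr, lt, years=(2018, 2050))
        assert py.sum() == pytest.approx(33.0)

    def test_constant_population_linear(self):
        qx = np.zeros(101)
        qx[-1] = 1.0
        lt = LifeTable(age=np.arange(101), qx=qx)
        count = np.zeros(101)
        count[20:40] = 7.0  # nobody reaches the terminal age by 2050
        pyr = PopulationPyramid(age=np.arange(101), count=count)
        py = person_years_projection(pyr, lt, years=(2018, 2050))
        assert py.sum() == pytest.approx(33 * 7.0 * 20)

    def test_matches_independent_projection(self, western):
        py = person_years_projection(western.pyramid, western.life_table, years=(2018, 2050))
        # independent cohort-component oracle, per single year of age
        lt, pyr = western.life_table, western.pyramid
        n = np.zeros(101)
        n[pyr.age] = pyr.count
        expected = 0.0
        for _ in range(33):
            deaths = n * lt.qx
            expected += (n - 0.5 * deaths)[40:101].sum()
            n2 = np.zeros_like(n)
            n2[1:] = (n - deaths)[:-1]
            n = n2
        got = py[:, 8:].sum()  # bands from age 40 up
        assert got == pytest.approx(expected, rel=1e-12)

    def test_person_years_scenario_invariant(self, small_run):
        western, _, raws, factors = small_run
        py = person_years_projection(western.pyramid, western.life_table)
        a = scale_to_population(raws["FIT"], factors, person_years=py)
        b = scale_to_population(raws["No screening"], factors, person_years=py)
        assert np.array_equal(a.person_years, b.person_years)


class TestPre2018Consistency:
    def test_pre_switch_screening_identical_across_scenarios(self, western):
        # extend the reporting window back so pre-2018 rounds are visible
        scenarios = [
            Scenario.current_programme(western, "FIT"),
            Scenario(
                "Colonoscopy",
                ProgrammeDesign(
                    test_name="colonoscopy", start_age=55, stop_age=75, interval=10,
                    participation=0.713, followup_adherence=0.85, start_year=2018,
                ),
            ),
        ]
        raws, _ = run_comparison(western, scenarios, n_sim=10_000, master_seed=21, years=(2014, 2024))
        pre = slice(0, 4)  # 2014-2017
        for metric in ("tests_FIT", "positives", "followup_colonoscopies", "adenomas_detected"):
            a = raws["FIT"].counts[metric][:, pre]
            b = raws["Colonoscopy"].counts[metric][:, pre]
            assert np.array_equal(a, b)
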