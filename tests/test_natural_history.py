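"""Natural-history sampling: death times, adenoma onsets, lesion
progression, clinical surfacing, CRC survival, and the agreement of the
Monte Carlo simulator with the deterministic incidence oracle."""

import numpy as np
import pytest
from scipy import stats

from crcsim.natural_history import (
    Lesion,
    PersonHistory,
    cohort_oracle,
    expected_band_cases,
    generate_cohort,
    progress_lesion,
    sample_adenoma_onsets,
    sample_crc_death,
    sample_death_ages,
    sample_other_cause_death,
    simulate_lesion_batch,
    surface_clinical,
)
from crcsim.params import LifeTable, LesionStateSpace, OnsetHazard, StageSurvival


def make_life_table(qx):
    qx = np.asarray(qx, dtype=float)
    return LifeTable(age=np.arange(len(qx)), qx=qx)


def make_space(p_progressive=1.0, growth=0.2, invade=0.25, stage_prog=0.6, surface=0.5):
    return LesionStateSpace(
        progression_rates={
            "adenoma_small": growth,
            "adenoma_medium": growth,
            "adenoma_large": invade,
            "preclinical_I": stage_prog,
            "preclinical_II": stage_prog,
            "preclinical_III": stage_prog,
        },
        surfacing_rates={s: surface for s in ("preclinical_I", "preclinical_II", "preclinical_III", "preclinical_IV")},
        p_progressive=p_progressive,
    )


class TestOtherCauseDeath:
    def test_forced_immediate_death(self, rng):
        lt = make_life_table([1.0])
        t = sample_other_cause_death(lt, 1950, rng)
        assert 1950.5 < t <= 1951.5  # age in (0, 1]

    def test_certain_survival_to_terminal_age(self, rng):
        qx = np.zeros(101)
        qx[-1] = 1.0
        ages = sample_death_ages(make_life_table(qx), 1000, rng)
        assert np.all((ages > 100.0) & (ages <= 101.0))

    def test_flat_hazard_mean_matches_geometric(self, rng):
        # age at death ~ geometric(p=0.02) year + uniform within-year 1/2
        p = 0.02
        qx = np.full(400, p)
        qx[-1] = 1.0
        n = 100_000
        ages = sample_death_ages(make_life_table(qx), n, rng)
        # mean of the (0-based) geometric is (1-p)/p, truncation at 400 negligible
        expected = (1 - p) / p + 0.5
        sd = np.sqrt((1 - p) / p**2)
        assert abs(ages.mean() - expected) < 3 * sd / np.sqrt(n)

    def test_conditioning_on_survival(self, rng):
        qx = np.full(120, 0.05)
        qx[-1] = 1.0
        ages = sample_death_ages(make_life_table(qx), 5000, rng, min_age=67.5)
        assert np.all(ages > 67.5)

    def test_missing_ages_error(self):
        with pytest.raises(Exception):
            make_life_table([0.1, 0.2])  # terminal qx != 1


class TestAdenomaOnsets:
    def test_zero_hazard_no_onsets(self, rng):
        oh = OnsetHazard(age=np.arange(100), hazard=np.zeros(100))
        assert len(sample_adenoma_onsets(oh, 80.0, rng)) == 0

    def test_poisson_mean_flat_hazard(self, rng):
        oh = OnsetHazard(age=np.arange(100), hazard=np.full(100, 0.01))
        n = 100_000
        counts = [len(sample_adenoma_onsets(oh, 80.0, rng)) for _ in range(2000)]
        # mean count = 0.01 * 80 = 0.8; use wider aggregate (2000 persons)
        assert abs(np.mean(counts) - 0.8) < 3 * np.sqrt(0.8 / len(counts))

    def test_piecewise_hazard_respects_support(self, rng):
        haz = np.where(np.arange(100) >= 40, 0.02, 0.0)
        oh = OnsetHazard(age=np.arange(100), hazard=haz)
        all_onsets = np.concatenate([sample_adenoma_onsets(oh, 80.0, rng) for _ in range(3000)])
        assert np.all(all_onsets >= 40.0)
        mean = len(all_onsets) / 3000
        lam = 0.02 * 40
        assert abs(mean - lam) < 3 * np.sqrt(lam / 3000)

    def test_negative_hazard_rejected(self):
        with pytest.raises(Exception):
            OnsetHazard(age=np.arange(10), hazard=np.full(10, -0.1))


class TestLesionProgression:
    def test_zero_rates_absorbing(self, rng):
        space = make_space(growth=0.0, invade=0.0)
        les = progress_lesion(50.0, space, 150.0, rng)
        assert np.isinf(les.entry_ages[1:]).all()
        assert les.state_at(120.0) == 0  # adenoma_small forever

    def test_nonprogressive_never_reach_preclinical(self, rng):
        space = make_space(p_progressive=0.0, growth=5.0, invade=5.0)
        out = simulate_lesion_batch(space, np.full(2000, 40.0), rng)
        assert np.isinf(out["entry_ages"][:, 3:]).all()
        assert not out["progressive"].any()
        assert (out["surface_stage"] == 0).all()

    def test_exponential_exit_from_first_state(self, rng):
        # departure from adenoma_small at rate 0.1: P(left by t=10) = 1 - e^-1
        space = make_space(growth=0.1)
        out = simulate_lesion_batch(space, np.zeros(20_000), rng)
        frac = np.mean(out["entry_ages"][:, 1] <= 10.0)
        p = 1 - np.exp(-1)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 20_000)

    def test_trajectory_entry_order(self, rng):
        space = make_space()
        out = simulate_lesion_batch(space, np.full(500, 30.0), rng)
        entries = out["entry_ages"]
        with np.errstate(invalid="ignore"):
            diffs = np.diff(entries, axis=1)  # inf - inf -> nan, masked below
        both_finite = np.isfinite(entries[:, :-1]) & np.isfinite(entries[:, 1:])
        assert np.all(diffs[both_finite] >= 0)
        # states are reached in order: no finite entry after an inf one
        reached = np.isfinite(entries)
        assert np.all(reached[:, :-1] >= reached[:, 1:])


class TestClinicalSurfacing:
    def test_adenoma_only_person_has_no_diagnosis(self):
        les = Lesion(onset_age=50, progressive=False, entry_ages=np.array([50.0] + [np.inf] * 6))
        p = PersonHistory(birth_year=1950, birth_time=1950.5, death_time_other=2040.0, lesions=[les])
        assert surface_clinical(p) is None

    def test_preclinical_sojourn_is_exponential(self, rng):
        # instant growth to preclinical_I, no stage progression: the dwell
        # before surfacing is Exp(sigma)
        space = make_space(growth=1e9, invade=1e9, stage_prog=0.0, surface=0.3)
        out = simulate_lesion_batch(space, np.zeros(10_000), rng)
        dwell = out["surface_age"] - out["entry_ages"][:, 3]
        res = stats.kstest(dwell, "expon", args=(0, 1 / 0.3))
        assert res.pvalue > 0.01

    def test_two_lesions_competing_risks(self):
        l1 = Lesion(onset_age=40, progressive=True, entry_ages=np.array([40.0] * 7), surface_age=63.0, surface_stage=2, clinical_stage=2)
        l2 = Lesion(onset_age=45, progressive=True, entry_ages=np.array([45.0] * 7), surface_age=59.0, surface_stage=1, clinical_stage=1)
        p = PersonHistory(birth_year=1950, birth_time=1950.5, death_time_other=2050.0, lesions=[l1, l2])
        dx = surface_clinical(p)
        assert dx == (1950.5 + 59.0, 1)


def uniform_survival():
    """Cumulative relative survival dropping linearly from 1 to 0 at 10y."""
    years = np.arange(11.0)
    drop = 1 - years / 10.0
    return StageSurvival(years=years, survival={s: drop for s in "I II III IV".split()})


class TestCrcSurvival:
    def test_full_relative_survival_means_cure(self, rng):
        years = np.arange(11.0)
        surv = StageSurvival(years=years, survival={s: np.ones(11) for s in "I II III IV".split()})
        assert sample_crc_death((2020.0, 2), surv, 2070.0, rng) is None

    def test_uniform_drop_five_year_mortality(self, rng):
        surv = uniform_survival()
        n = 10_000
        t = surv.inverse_cdf("I", rng.random(n))
        frac5 = np.mean(t <= 5.0)
        assert abs(frac5 - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_stage_ordering_of_mean_survival(self, rng, western):
        surv = western.survival
        n = 10_000
        u = rng.random(n)
        t1 = surv.inverse_cdf("I", u)
        t4 = surv.inverse_cdf("IV", u)
        assert np.mean(np.minimum(t4, 10)) < np.mean(np.minimum(t1, 10))

    def test_table_must_cover_horizon(self):
        with pytest.raises(Exception):
            StageSurvival(years=np.arange(6.0), survival={s: np.linspace(1, 0.5, 6) for s in "I II III IV".split()})


class TestCohortOracle:
    def test_zero_onset_zero_incidence(self, western):
        from dataclasses import replace

        p = replace(western, onset=OnsetHazard(age=np.arange(100), hazard=np.zeros(100)))
        assert np.all(cohort_oracle(p) == 0.0)

    def test_step_halving_convergence(self, western):
        a = cohort_oracle(western, dt=0.02)
        b = cohort_oracle(western, dt=0.01)
        mask = b > 1e-6
        assert np.max(np.abs(a[mask] - b[mask]) / b[mask]) < 1e-3

    def test_monte_carlo_matches_oracle(self, western):
        # immortal cohort so every person-year is at risk until diagnosis
        inc = cohort_oracle(western, dt=0.02)
        n = 60_000
        co = generate_cohort(western, 1950, n, master_seed=5, immortal=True)
        d = co.first_surface_age
        py = np.array([np.clip(np.minimum(d, a + 1) - a, 0, 1).sum() for a in range(100)])
        bands = [(a, a + 5) for a in range(40, 100, 5)]
        obs = np.array([((d >= lo) & (d < hi)).sum() for lo, hi in bands])
        exp = expected_band_cases(inc, py, bands)
        z = (obs - exp) / np.sqrt(exp)
        assert np.max(np.abs(z)) < 4.0  # wider bands at this n

    def test_determinism_bitwise(self, western):
        a = generate_cohort(western, 1955, 2000, master_seed=9)
        b = generate_cohort(western, 1955, 2000, master_seed=9)
        assert np.array_equal(a.death_age_other, b.death_age_other)
        assert np.array_equal(a.lesions.onset_age, b.lesions.onset_age)
        assert np.array_equal(a.lesions.surface_age, b.lesions.surface_age)
        assert np.array_equal(a.u_survival, b.u_survival)

    def test_conservation_every_case_has_a_preclinical_lesion(self, western):
        co = generate_cohort(western, 1950, 20_000, master_seed=3)
        les = co.lesions
        surf = np.isfinite(les.surface_age)
        # every surfacing lesion passed through at least preclinical_I
        assert np.all(np.isfinite(les.entry_ages[surf, 3]))
        # and no event precedes lesion onset
        assert np.all(les.surface_age[surf] > les.onset_age[surf])
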