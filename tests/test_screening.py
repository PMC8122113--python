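"""Screening overlay: invitation schedules, attendance, test
application, positive resolution, complications, and the accounting
chain on simulated programmes."""

import numpy as np
import pytest

from crcsim.natural_history import PersonHistory
from crcsim.params import (
    STATE_INDEX,
    ProgrammeDesign,
    ScreeningTest,
    SurveillanceProtocol,
)
from crcsim.screening import (
    apply_test,
    build_invitation_schedule,
    classify_findings,
    resolve_positive,
    sample_complications,
    simulate_attendance,
)


def person(birth_year=1959, death_age=90.0, lesions=()):
    return PersonHistory(
        birth_year=birth_year,
        birth_time=birth_year + 0.5,
        death_time_other=birth_year + 0.5 + death_age,
        lesions=list(lesions),
    )


def design(**kw):
    base = dict(
        test_name="FIT",
        start_age=55,
        stop_age=75,
        interval=2,
        participation=0.713,
        invitation_coverage=1.0,
        followup_adherence=0.85,
        start_year=2014,
    )
    base.update(kw)
    return ProgrammeDesign(**base)


class TestInvitationSchedule:
    def test_biennial_55_to_75_gives_eleven_rounds(self):
        # born 1959: age 55 reached in 2014, the programme's first year
        p = person(birth_year=1959, death_age=90.0)
        inv = build_invitation_schedule(design(), p)
        assert len(inv) == 11
        ages = [t - p.birth_time for t in inv]
        assert ages == [55 + 2 * k for k in range(11)]

    def test_death_before_start_age_means_no_invitations(self):
        p = person(birth_year=1959, death_age=54.0)
        assert build_invitation_schedule(design(), p) == []

    def test_decennial_interval(self):
        p = person(birth_year=1959, death_age=95.0)
        inv = build_invitation_schedule(design(interval=10), p)
        assert [t - p.birth_time for t in inv] == [55, 65, 75]

    def test_no_invitations_after_clinical_diagnosis(self):
        p = person(birth_year=1959, death_age=90.0)
        p.clinical_dx = (p.birth_time + 60.0, 2)
        inv = build_invitation_schedule(design(), p)
        assert all(t < p.clinical_dx[0] for t in inv)
        assert len(inv) == 3  # 55, 57, 59

    def test_calendar_restriction(self):
        # born 1949: ages 55-64 fall before the 2014 programme start
        p = person(birth_year=1949, death_age=90.0)
        inv = build_invitation_schedule(design(), p)
        assert min(t - p.birth_time for t in inv) == 65


class TestAttendance:
    def test_zero_participation(self, rng):
        inv = list(range(10))
        assert simulate_attendance(inv, design(participation=0.0), rng) == []

    def test_full_participation_and_coverage(self, rng):
        inv = list(range(10))
        assert simulate_attendance(inv, design(participation=1.0), rng) == inv

    def test_attendance_rate_binomial(self, rng):
        p = 0.713
        n = 100_000
        att = simulate_attendance(list(range(n)), design(participation=p), rng)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(len(att) / n - p) < 3 * se


def fit_test(**kw):
    base = dict(
        name="FIT",
        sensitivity_by_state={
            "adenoma_small": 0.05,
            "adenoma_medium": 0.1,
            "adenoma_large": 0.3,
            "preclinical_I": 0.7,
            "preclinical_II": 0.75,
            "preclinical_III": 0.8,
            "preclinical_IV": 0.85,
        },
        specificity=0.95,
    )
    base.update(kw)
    return ScreeningTest(**base)


class TestApplyTest:
    def test_lesion_free_perfect_specificity_always_negative(self, rng):
        t = fit_test(specificity=1.0)
        for _ in range(100):
            r = apply_test(np.empty(0, dtype=int), t, rng)
            assert not r.positive and not r.false_positive

    def test_perfect_sensitivity_detects_preclinical(self, rng):
        t = fit_test(sensitivity_by_state={s: 1.0 for s in STATE_INDEX})
        r = apply_test(np.array([STATE_INDEX["preclinical_II"]]), t, rng)
        assert r.positive and r.detected.all() and not r.false_positive

    def test_false_positive_rate_matches_one_minus_specificity(self, rng):
        t = fit_test(specificity=0.95)
        n = 100_000
        pos = sum(apply_test(np.empty(0, dtype=int), t, rng).positive for _ in range(n))
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(pos / n - 0.05) < 3 * se

    def test_missing_sensitivity_entry_is_zero_filled(self):
        # the container normalizes a partial sensitivity map
        t = ScreeningTest(name="x", sensitivity_by_state={"preclinical_IV": 1.0}, specificity=1.0)
        assert t.sensitivity_by_state["adenoma_small"] == 0.0


def colonoscopy(**kw):
    base = dict(
        name="colonoscopy",
        sensitivity_by_state={s: 0.95 for s in STATE_INDEX},
        specificity=1.0,
        complication_probs={"serious": 0.002, "cardiovascular": 0.001, "other": 0.012},
        is_direct_visualization=True,
    )
    base.update(kw)
    return ScreeningTest(**base)


class _Recorder:
    def __init__(self):
        self.events = []

    def __call__(self, time, event, test_name="", count=1):
        self.events.append((time, event, count))

    def count(self, name):
        return sum(c for _, e, c in self.events if e == name)


class TestResolvePositive:
    def test_zero_adherence_leaves_lesions_untouched(self, rng):
        rec = _Recorder()
        removed, stage, findings = resolve_positive(
            2020.0,
            np.array([0]),
            np.array([STATE_INDEX["adenoma_large"]]),
            design(followup_adherence=0.0),
            colonoscopy(),
            SurveillanceProtocol(),
            rng,
            rec,
        )
        assert len(removed) == 0 and stage == 0 and findings is None
        assert rec.count("followup_colonoscopy") == 0

    def test_certain_followup_removes_large_adenoma(self, rng):
        colo = colonoscopy(sensitivity_by_state={s: 1.0 for s in STATE_INDEX}, complication_probs={})
        rec = _Recorder()
        removed, stage, findings = resolve_positive(
            2020.0,
            np.array([3]),
            np.array([STATE_INDEX["adenoma_large"]]),
            design(followup_adherence=1.0),
            colo,
            SurveillanceProtocol(),
            rng,
            rec,
        )
        assert list(removed) == [3]
        assert stage == 0
        assert findings == "high"  # a large adenoma is a high-risk finding
        assert rec.count("adenoma_detected") == 1

    def test_followup_ratio_matches_adherence(self, rng):
        d = design(followup_adherence=0.85)
        colo = colonoscopy(complication_probs={})
        n = 10_000
        rec = _Recorder()
        for _ in range(n):
            resolve_positive(
                2020.0, np.empty(0, dtype=int), np.empty(0, dtype=int), d, colo,
                SurveillanceProtocol(), rng, rec,
            )
        frac = rec.count("followup_colonoscopy") / n
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(frac - 0.85) < 3 * se

    def test_detected_preclinical_cancer_is_screen_detected_at_stage(self, rng):
        colo = colonoscopy(sensitivity_by_state={s: 1.0 for s in STATE_INDEX}, complication_probs={})
        rec = _Recorder()
        removed, stage, findings = resolve_positive(
            2020.0,
            np.array([0, 1]),
            np.array([STATE_INDEX["adenoma_small"], STATE_INDEX["preclinical_III"]]),
            design(followup_adherence=1.0),
            colo,
            SurveillanceProtocol(),
            rng,
            rec,
        )
        assert stage == 3
        assert rec.count("cancer_detected") == 1


class TestComplications:
    def test_zero_probabilities(self, rng):
        t = colonoscopy(complication_probs={})
        counts = sample_complications(10_000, t, rng)
        assert all(v == 0 for v in counts.values())

    def test_binomial_count(self, rng):
        t = colonoscopy(complication_probs={"serious": 0.005})
        n = 100_000
        counts = sample_complications(n, t, rng)
        se = np.sqrt(n * 0.005 * 0.995)
        assert abs(counts["serious"] - 500) < 3 * se

    def test_linearity_in_volume(self, rng):
        t = colonoscopy(complication_probs={"other": 0.01})
        reps = 200
        small = np.mean([sample_complications(1000, t, rng)["other"] for _ in range(reps)])
        big = np.mean([sample_complications(2000, t, rng)["other"] for _ in range(reps)])
        assert abs(big - 2 * small) < 4 * np.sqrt(2000 * 0.01) / np.sqrt(reps) * 2


class TestFindingsClassification:
    def test_no_adenomas(self):
        assert classify_findings(np.empty(0, dtype=int), SurveillanceProtocol()) is None

    @pytest.mark.parametrize(
        "states,expected",
        [
            ([STATE_INDEX["adenoma_small"]], "low"),
            ([STATE_INDEX["adenoma_large"]], "high"),
            ([STATE_INDEX["adenoma_small"]] * 3, "high"),
            ([STATE_INDEX["adenoma_small"], STATE_INDEX["adenoma_medium"]], "low"),
        ],
    )
    def test_risk_classes(self, states, expected):
        assert classify_findings(np.array(states), SurveillanceProtocol()) == expected
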